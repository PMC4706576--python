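"""File I/O: binary masks (PNG / single-slice NIfTI) and cohort CSV tables.

Cohort CSV schema: subject_id, group, age, w01..w99 [, area, perimeter,
centreline_length, convergence_iters].  Widths are mm.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CCError
from .geometry import MidsagittalMask, WidthProfile
from .synthetic import CohortWidths

WIDTH_COLS = [f"w{i:02d}" for i in range(1, 100)]


def load_mask(path, spacing: tuple[float, float] | None = None) -> MidsagittalMask:
    """Load a PNG (nonzero = foreground) or single-slice NIfTI mask.

    PNG carries no physical spacing, so ``spacing`` (row_mm, col_mm) is
    required; NIfTI spacing defaults to the header pixdim.
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise CCError("bad-mask", "NIfTI mask must be a single slice")
        if spacing is None:
            zooms = img.header.get_zooms()
            spacing = (float(zooms[0]), float(zooms[1]))
        return MidsagittalMask(grid=data > 0, spacing=spacing)
    if suffix.endswith(".png"):
        from PIL import Image
        arr = np.array(Image.open(path).convert("L"))
        if spacing is None:
            raise CCError("bad-spacing", "PNG masks need an explicit spacing")
        return MidsagittalMask(grid=arr > 0, spacing=spacing)
    raise CCError("bad-mask", f"unsupported mask format: {path.name}")


def save_mask_png(mask: MidsagittalMask, path) -> None:
    from PIL import Image
    Image.fromarray((mask.grid * 255).astype(np.uint8)).save(str(path))


def profile_row(subject_id: str, profile: WidthProfile) -> dict:
    """One cohort-CSV row for an extracted width profile."""
    row = {"subject_id": subject_id}
    row.update({c: w for c, w in zip(WIDTH_COLS, profile.widths)})
    row.update(area=profile.area, perimeter=profile.perimeter,
               centreline_length=profile.centreline_length,
               convergence_iters=profile.iterations)
    return row


def cohort_to_frame(cohort: CohortWidths) -> pd.DataFrame:
    df = pd.DataFrame(cohort.matrix, columns=WIDTH_COLS)
    df.insert(0, "subject_id", cohort.subject_id)
    df.insert(1, "group", cohort.group)
    df.insert(2, "age", cohort.age)
    if cohort.pairing is not None:
        df["pair"] = cohort.pairing
    return df


def write_cohort_csv(cohort: CohortWidths, path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> CohortWidths:
    df = pd.read_csv(path)
    missing = [c for c in WIDTH_COLS if c not in df.columns]
    if missing:
        raise CCError("bad-cohort", f"missing width columns: {missing[:3]}...")
    if df[WIDTH_COLS].isna().any().any():
        raise CCError("bad-cohort", "missing width values")
    return CohortWidths(
        matrix=df[WIDTH_COLS].to_numpy(dtype=float),
        group=df["group"].to_numpy() if "group" in df else
        np.array(["unknown"] * len(df)),
        age=df["age"].to_numpy(dtype=float) if "age" in df else
        np.full(len(df), np.nan),
        pairing=df["pair"].to_numpy() if "pair" in df else None,
        subject_id=df["subject_id"].astype(str).to_numpy()
        if "subject_id" in df else None)
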