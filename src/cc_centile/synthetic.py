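"""Synthetic corpus-callosum width cohorts and rendered masks.

The generator emulates the statistical structure the analysis chain
assumes: a CC-like baseline width profile (thick genu, thin mid-body,
thick splenium, tapered ends), smooth regional covariance driven by
latent per-region factors, a small global size factor, independent
per-centile measurement noise, and a focal case–control thinning effect
in the genu (centiles 8–15) and the mid-posterior body (centiles 61–70)
peaking at 1.47 mm at centile 63.

Cohorts are age-matched case/control pairs (13 vs 13 by default).  The
per-centile noise and regional-factor scales are calibrated so that, as
in the motivating clinical setting, no single centile survives a
Bonferroni-corrected comparison at n = 13 + 13 while the factor-level
ANOVA and a multivariate linear-SVM classifier still separate the
groups.  See docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import CCError, CCWarning
from .geometry import MidsagittalMask

__all__ = [
    "Region",
    "EffectSpec",
    "GeneratorConfig",
    "EffectProfile",
    "CohortWidths",
    "baseline_width_curve",
    "effect_profile",
    "generate_cohort",
    "render_mask",
]

CENTILES = np.arange(1, 100)


@dataclass(frozen=True)
class Region:
    """Contiguous centile range [lo, hi] assigned to one latent factor."""
    lo: int
    hi: int


@dataclass(frozen=True)
class EffectSpec:
    """One focal thinning dip: nonzero on [lo, hi], maximal at ``peak``."""
    lo: int
    hi: int
    peak: int
    peak_mm: float


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator, with the default study conditions.

    Thickness parameters are mm; ``scale_sd`` is the log-sd of the
    lognormal global size factor (a fraction); ``effect_jitter`` is the
    relative between-subject sd of the thinning effect.
    """

    n_case: int = 13
    n_control: int = 13
    # baseline profile (mm)
    genu_mm: float = 11.0
    body_mm: float = 6.0
    splenium_mm: float = 10.0
    taper_mm: float = 2.0
    genu_center: float = 0.10
    splenium_center: float = 0.90
    bump_width: float = 0.08
    taper_exponent: float = 0.35
    # latent covariance structure: genu, anterior body, mid body,
    # mid-posterior body, posterior body, splenium
    regions: tuple = (Region(5, 17), Region(18, 34), Region(35, 56),
                      Region(57, 69), Region(70, 84), Region(85, 95))
    end_taper_zones: tuple = (Region(1, 4), Region(96, 99))
    regional_sd: tuple = (1.5, 0.9, 0.9, 0.9, 0.95, 1.3)  # mm per region
    taper_sd: float = 1.0          # mm, end-taper factor sd
    scale_sd: float = 0.26         # lognormal sigma of global size
    noise_sd: float = 0.1          # mm, independent per-centile noise
    # group effect (case minus control is -delta)
    effects: tuple = (EffectSpec(8, 15, 11, 1.30),
                      EffectSpec(61, 70, 63, 1.47))
    effect_jitter: float = 0.20
    # ages (years)
    age_min: float = 1.0
    age_max: float = 15.0
    age_match_jitter: float = 0.5
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


@dataclass
class EffectProfile:
    """Expected case-minus-control mean width difference per centile."""
    delta: np.ndarray  # (99,), mm; negative values mean thinning

    @property
    def max_abs(self) -> float:
        return float(np.abs(self.delta).max())

    @property
    def argmax_centile(self) -> int:
        return int(np.abs(self.delta).argmax()) + 1


@dataclass
class CohortWidths:
    """Subjects × 99 width matrix with labels, ages and case↔control pairing."""

    matrix: np.ndarray            # (n, 99) mm
    group: np.ndarray             # (n,) "case" | "control"
    age: np.ndarray               # (n,) years
    pairing: np.ndarray | None = None  # (n,) match index, or None
    subject_id: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 99:
            raise CCError("bad-cohort", "width matrix must be n x 99")
        if self.subject_id is None:
            self.subject_id = np.array(
                [f"S{i:03d}" for i in range(len(self.matrix))])

    @property
    def case_mask(self) -> np.ndarray:
        return np.asarray(self.group) == "case"

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(case matrix, control matrix), paired order when pairing exists."""
        m = self.case_mask
        cases, controls = self.matrix[m], self.matrix[~m]
        if self.pairing is not None:
            order = np.argsort(self.pairing[m])
            cases = cases[order]
            controls = controls[np.argsort(self.pairing[~m])]
        return cases, controls


# ---------------------------------------------------------------------------
# baseline and effect curves
# ---------------------------------------------------------------------------

def baseline_width_curve(t, config: GeneratorConfig | None = None):
    """Template callosal width (mm) at axis fraction ``t`` in [0, 1].

    A sine-envelope taper (value ``taper_mm`` at the tips, ``body_mm`` at
    mid-body) plus Gaussian bumps for the genu and splenium.  With a
    symmetric configuration (genu == splenium) the curve is symmetric
    about t = 0.5.
    """
    cfg = config or GeneratorConfig()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > 1):
        raise CCError("bad-fraction", "t must lie in [0, 1]")
    env = cfg.taper_mm + (cfg.body_mm - cfg.taper_mm) * np.sin(np.pi * t) ** cfg.taper_exponent
    genu = (cfg.genu_mm - cfg.body_mm) * np.exp(
        -((t - cfg.genu_center) / cfg.bump_width) ** 2)
    splen = (cfg.splenium_mm - cfg.body_mm) * np.exp(
        -((t - cfg.splenium_center) / cfg.bump_width) ** 2)
    return env + genu + splen


def _raised_cosine_dip(centiles: np.ndarray, eff: EffectSpec) -> np.ndarray:
    """Smooth bump: 0 outside [lo, hi], exactly ``peak_mm`` at ``peak``."""
    c = centiles.astype(float)
    out = np.zeros_like(c)
    left = (c >= eff.lo) & (c <= eff.peak)
    right = (c > eff.peak) & (c <= eff.hi)
    # support reaches one centile beyond the range so the range ends are > 0
    s_l = (c[left] - (eff.lo - 1)) / (eff.peak - (eff.lo - 1))
    s_r = ((eff.hi + 1) - c[right]) / ((eff.hi + 1) - eff.peak)
    out[left] = 0.5 * (1 - np.cos(np.pi * s_l))
    out[right] = 0.5 * (1 - np.cos(np.pi * s_r))
    return eff.peak_mm * out


def effect_profile(config: GeneratorConfig | None = None) -> EffectProfile:
    """Expected mean thinning (mm) per centile under the configured effects."""
    cfg = config or GeneratorConfig()
    delta = np.zeros(99)
    for eff in cfg.effects:
        if not (1 <= eff.lo <= eff.peak <= eff.hi <= 99):
            raise CCError("bad-effect",
                          f"peak {eff.peak} outside range {eff.lo}-{eff.hi}")
        delta -= _raised_cosine_dip(CENTILES, eff)
    return EffectProfile(delta=delta)


# ---------------------------------------------------------------------------
# latent factor loadings
# ---------------------------------------------------------------------------

def _bump_loading(centiles: np.ndarray, lo: int, hi: int,
                  shoulder: float = 2.0) -> np.ndarray:
    """Raised-cosine bump peaked at the region centre, zero beyond the
    region edges plus a small shoulder.

    Peaked (rather than blocky) loadings mimic smooth between-subject
    regional covariance and overlap neighbouring regions so that no
    centile is left factor-free.
    """
    c = centiles.astype(float)
    m = 0.5 * (lo + hi)
    w = (hi - lo) / 2.0 + shoulder + 1.0
    out = 0.5 * (1.0 + np.cos(np.pi * (c - m) / w))
    out[np.abs(c - m) >= w] = 0.0
    return out


def factor_loadings(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """(n_factor × 99 loading curves, per-factor sd vector).

    One bump per contiguous region plus a single end-taper factor loading
    on both extreme zones.  Regional bumps are modulated by the local
    baseline thickness (thick regions vary more in absolute mm than thin
    ones) and re-normalized to peak 1, so the per-factor sd keeps its
    meaning of "mm at the region's thickest point".
    """
    base = baseline_width_curve(CENTILES / 100.0, config)
    rows = []
    for r in config.regions:
        bump = _bump_loading(CENTILES, r.lo, r.hi) * base
        rows.append(bump / bump.max())
    taper = np.zeros(99)
    for z in config.end_taper_zones:
        taper += _bump_loading(CENTILES, z.lo, z.hi, shoulder=3.0)
    rows.append(np.clip(taper, 0, 1))
    rsd = config.regional_sd
    if np.isscalar(rsd):
        rsd = (float(rsd),) * len(config.regions)
    if len(rsd) != len(config.regions):
        raise CCError("bad-config", "regional_sd must match region count")
    sds = np.array(list(rsd) + [config.taper_sd])
    return np.asarray(rows), sds


def designed_partition(config: GeneratorConfig) -> np.ndarray:
    """Designed factor index (0-based) per centile: argmax of the loadings."""
    L, _ = factor_loadings(config)
    return np.argmax(L, axis=0)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> CohortWidths:
    """Draw one age-matched case/control cohort of 99-centile width profiles.

    subject widths = scale · (baseline + Σ_r a_r L_r) + ε − [case] δ·(1+j),
    with a_r ~ N(0, regional sd), ε ~ N(0, noise sd) per centile, scale
    lognormal, and j ~ N(0, effect_jitter) per case subject.  Widths are
    floored at 0.5 mm (warning; error if > 5% of values are floored).
    Fully reproducible from the seed.
    """
    cfg = config or GeneratorConfig()
    if seed is not None:
        cfg = GeneratorConfig(**{**asdict(cfg), "seed": seed,
                                 "regions": cfg.regions,
                                 "end_taper_zones": cfg.end_taper_zones,
                                 "effects": cfg.effects})
    if cfg.n_case < 2 or cfg.n_control < 2:
        raise CCError("bad-cohort", "need >= 2 subjects per group")
    rng = np.random.default_rng(cfg.seed)

    base = baseline_width_curve(CENTILES / 100.0, cfg)
    L, sds = factor_loadings(cfg)
    delta = -effect_profile(cfg).delta  # positive thinning amounts

    n = cfg.n_case + cfg.n_control
    a = rng.standard_normal((n, len(sds))) * sds
    scale = np.exp(rng.standard_normal(n) * cfg.scale_sd)
    eps = rng.standard_normal((n, 99)) * cfg.noise_sd
    jit = rng.standard_normal(cfg.n_case) * cfg.effect_jitter

    widths = scale[:, None] * (base[None, :] + a @ L) + eps
    widths[:cfg.n_case] -= delta[None, :] * (1.0 + jit)[:, None]

    clipped = widths < 0.5
    if clipped.any():
        rate = clipped.mean()
        if rate > 0.05:
            raise CCError("noise-too-large",
                          f"{rate:.1%} of widths fell below the 0.5 mm floor")
        warnings.warn(f"{clipped.sum()} widths floored at 0.5 mm", CCWarning)
        widths = np.maximum(widths, 0.5)

    case_age = rng.uniform(cfg.age_min, cfg.age_max, cfg.n_case)
    n_pairs = min(cfg.n_case, cfg.n_control)
    ctrl_age = rng.uniform(cfg.age_min, cfg.age_max, cfg.n_control)
    ctrl_age[:n_pairs] = case_age[:n_pairs] + rng.uniform(
        -cfg.age_match_jitter, cfg.age_match_jitter, n_pairs)

    group = np.array(["case"] * cfg.n_case + ["control"] * cfg.n_control)
    pairing = None
    if cfg.n_case == cfg.n_control:
        pairing = np.concatenate([np.arange(cfg.n_case), np.arange(cfg.n_control)])
    return CohortWidths(matrix=widths, group=group,
                        age=np.concatenate([case_age, ctrl_age]),
                        pairing=pairing)


# ---------------------------------------------------------------------------
# mask rendering
# ---------------------------------------------------------------------------

def render_mask(widths: np.ndarray, spacing: float = 0.25,
                arch_radius_mm: float = 30.0, arch_degrees: float = 150.0,
                arch_length_mm: float | None = None,
                margin_mm: float = 4.0) -> MidsagittalMask:
    """Rasterize a 99-centile width profile as a CC-like arched band.

    The profile is swept perpendicular to a circular-arc centreline
    (default 150° of a 30 mm circle, opening downward, anterior on the
    left), widths interpolated between the centile stations at arc
    fractions k/100 and tapered to a point at both tips.  An infinite
    ``arch_radius_mm`` gives a straight sweep of length
    ``arch_length_mm``.
    """
    widths = np.asarray(widths, dtype=float)
    if widths.shape != (99,):
        raise CCError("bad-profile", "expected 99 widths")
    if np.any(widths <= 0):
        raise CCError("bad-profile", "widths must be positive")
    if widths.max() >= 2.0 * arch_radius_mm:
        raise CCError("sweep-fold",
                      "width exceeds twice the centreline radius of curvature")

    s = np.linspace(0.0, 1.0, 600)
    if np.isinf(arch_radius_mm):
        if arch_length_mm is None:
            raise CCError("bad-config",
                          "straight sweep needs arch_length_mm")
        centre = np.column_stack([s * arch_length_mm, np.zeros_like(s)])
        normal = np.tile([0.0, 1.0], (len(s), 1))
    else:
        half = np.radians(arch_degrees) / 2.0
        ang = np.pi / 2 + half - s * 2 * half  # left tip -> right tip, apex up
        centre = arch_radius_mm * np.column_stack([np.cos(ang), np.sin(ang)])
        # outward (dorsal) normal of the circular arc is the radial direction
        normal = np.column_stack([np.cos(ang), np.sin(ang)])

    stations = np.concatenate([[0.0], np.arange(1, 100) / 100.0, [1.0]])
    w_nodes = np.concatenate([[0.0], widths, [0.0]])  # taper closed at tips
    w = np.interp(s, stations, w_nodes)

    upper = centre + 0.5 * w[:, None] * normal
    lower = centre - 0.5 * w[:, None] * normal
    ring = np.vstack([upper, lower[::-1]])

    xmin, ymin = ring.min(axis=0) - margin_mm
    xmax, ymax = ring.max(axis=0) + margin_mm
    ncol = int(np.ceil((xmax - xmin) / spacing))
    nrow = int(np.ceil((ymax - ymin) / spacing))
    col = (ring[:, 0] - xmin) / spacing
    row = (ymax - ring[:, 1]) / spacing

    from skimage.draw import polygon as draw_polygon
    rr, cc = draw_polygon(row, col, shape=(nrow, ncol))
    grid = np.zeros((nrow, ncol), dtype=bool)
    grid[rr, cc] = True
    return MidsagittalMask(grid=grid, spacing=(spacing, spacing))
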