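"""Varimax-rotated PCA regionalization of the 99 centile widths.

The 99 widths are highly correlated between neighbouring centiles, so
the cohort matrix is reduced to a handful of components: PCA on the
column-standardized widths (correlation-matrix PCA, so the factors are
normalised to overall callosal size), retention of every component
explaining more than 1% of the total variance, varimax rotation towards
simple structure, assignment of each centile to the factor with the
largest absolute rotated loading, and regression-method subject scores
(mean zero per factor by construction).

A factor whose assigned centiles fall mostly in the extreme ends of the
profile (centiles 1–4 and 96–99) reflects the tapering shape of the
tips rather than an anatomical region; it is flagged as "end-taper" and
excluded from group comparison by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import CCError, CCWarning
from .synthetic import CohortWidths

__all__ = [
    "RegionalFactors",
    "pca",
    "retain_components",
    "varimax",
    "assign_regions",
    "factor_scores",
    "regionalize",
    "contiguous_runs",
]


@dataclass
class RegionalFactors:
    """Retained rotated loadings, centile→region map and subject scores."""

    loadings: np.ndarray            # (99, k) rotated
    explained_fraction: np.ndarray  # (k,) of total variance, unrotated order
    region_of_centile: np.ndarray   # (99,) values in 1..k
    scores: np.ndarray              # (n_subjects, k)
    retained_k: int
    end_taper_factors: np.ndarray   # indices (0-based) flagged as end-taper

    @property
    def anatomical_factors(self) -> np.ndarray:
        """Factor indices (0-based) kept for group comparison."""
        return np.array([j for j in range(self.retained_k)
                         if j not in set(self.end_taper_factors)])


def _standardize(matrix: np.ndarray) -> np.ndarray:
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise CCError("constant-centile",
                      f"zero-variance centile(s): {np.where(sd <= 0)[0] + 1}")
    return (matrix - mu) / sd


def pca(widths: CohortWidths) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlation-matrix PCA of the width matrix.

    Returns (eigenvectors as columns, eigenvalues, explained fraction),
    components ordered by non-increasing eigenvalue.  Explained fraction
    is eigenvalue / 99 (the trace of a correlation matrix).
    """
    X = widths.matrix
    if len(X) < 3:
        raise CCError("bad-cohort", "PCA needs at least 3 subjects")
    Z = _standardize(X)
    corr = (Z.T @ Z) / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    return eigvec, eigval, eigval / corr.shape[0]


def retain_components(explained_fraction: np.ndarray,
                      threshold: float = 0.01) -> int:
    """Number of components explaining strictly more than the threshold."""
    frac = np.asarray(explained_fraction)
    k = int(np.sum(frac > threshold))
    if k == 0:
        raise CCError("nothing-retained", "no component above the threshold")
    return k


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Orthogonal varimax rotation of a p × k loading matrix.

    Maximizes the varimax criterion (sum over factors of the variance of
    squared loadings, row-normalized by communality when Kaiser
    normalization is on) by cyclic pairwise Jacobi rotations with the
    analytically optimal angle per pair; sweeps repeat until the
    criterion's relative change drops below ``tol``.  Communalities are
    invariant under the orthogonal rotation.  Each rotated column is
    sign-flipped so its largest-|loading| entry is positive.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise CCError("bad-loadings", "loadings must be 2-D")
    p, k = L.shape
    if k == 1:
        return L.copy()

    comm = np.sqrt(np.sum(L ** 2, axis=1))
    if kaiser_normalize:
        safe = np.where(comm > 0, comm, 1.0)
        L = L / safe[:, None]

    def criterion(B):
        B2 = B ** 2
        return float(np.sum(B2 ** 2) - np.sum(B2.sum(axis=0) ** 2) / p)

    rotated = L.copy()
    crit = criterion(rotated)
    for _ in range(max_iter):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = rotated[:, i], rotated[:, j]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                num = 2.0 * (np.sum(u * v) - np.sum(u) * np.sum(v) / p)
                den = np.sum(u ** 2 - v ** 2) \
                    - (np.sum(u) ** 2 - np.sum(v) ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rotated[:, i], rotated[:, j] = c * x + s * y, -s * x + c * y
        new_crit = criterion(rotated)
        if new_crit - crit <= tol * max(abs(crit), 1.0):
            break
        crit = new_crit
    if kaiser_normalize:
        rotated = rotated * np.where(comm > 0, comm, 1.0)[:, None]
    # sign convention: dominant loading positive per column
    for j in range(k):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
    return rotated


def assign_regions(rotated: np.ndarray) -> np.ndarray:
    """Map each centile to the factor with the largest |loading| (1-based).

    Exact ties go to the lower factor index, with a warning.
    """
    A = np.abs(rotated)
    region = np.argmax(A, axis=1)
    ties = np.sum(A == A.max(axis=1, keepdims=True), axis=1) > 1
    if ties.any():
        warnings.warn(
            f"loading ties at centile(s) {np.where(ties)[0] + 1}; "
            "assigned to the lower factor index", CCWarning)
    return region + 1


def contiguous_runs(region_of_centile: np.ndarray) -> dict[int, list[tuple[int, int]]]:
    """Maximal contiguous centile runs per region (contiguity is reported,
    never enforced)."""
    runs: dict[int, list[tuple[int, int]]] = {}
    r = np.asarray(region_of_centile)
    start = 0
    for i in range(1, len(r) + 1):
        if i == len(r) or r[i] != r[start]:
            runs.setdefault(int(r[start]), []).append((start + 1, i))
            start = i
    return runs


def factor_scores(widths: CohortWidths, rotated: np.ndarray,
                  ridge: float = 1e-8) -> np.ndarray:
    """Regression-method (Thurstone) factor scores.

    scores = Z R⁻¹ Λ with Z the standardized widths, R their sample
    correlation matrix and Λ the rotated loadings.  A singular R (always
    the case when subjects < centiles) is ridge-stabilized with epsilon
    ``ridge`` on the diagonal, with a warning.  Each score column has
    mean zero because Z is column-centred.
    """
    Z = _standardize(widths.matrix)
    corr = (Z.T @ Z) / (len(Z) - 1)
    p = corr.shape[0]
    eigmin = np.linalg.eigvalsh(corr)[0]
    if eigmin < 1e-10:
        warnings.warn("singular correlation matrix; ridge-stabilized inverse",
                      CCWarning)
        corr = corr + ridge * np.eye(p)
    weights = np.linalg.solve(corr, rotated)
    return Z @ weights


def regionalize(widths: CohortWidths, threshold: float = 0.01,
                kaiser_normalize: bool = True,
                end_taper_zone: tuple = ((1, 4), (96, 99)),
                ) -> RegionalFactors:
    """Full chain: PCA → retention → varimax → regions → scores.

    Factors with more than half of their assigned centiles inside the
    extreme-end zones are flagged as end-taper factors.
    """
    eigvec, eigval, frac = pca(widths)
    k = retain_components(frac, threshold)
    loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
    rotated = varimax(loadings, kaiser_normalize=kaiser_normalize)
    region = assign_regions(rotated)
    scores = factor_scores(widths, rotated)

    end_mask = np.zeros(99, dtype=bool)
    for lo, hi in end_taper_zone:
        end_mask[lo - 1:hi] = True
    flagged = []
    for j in range(k):
        assigned = region == j + 1
        if assigned.any() and end_mask[assigned].mean() > 0.5:
            flagged.append(j)
    return RegionalFactors(
        loadings=rotated, explained_fraction=frac[:k],
        region_of_centile=region, scores=scores, retained_k=k,
        end_taper_factors=np.asarray(flagged, dtype=int))
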