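"""Centile-width geometry of a mid-sagittal corpus callosum mask.

The corpus callosum appears on the mid-sagittal plane as an elongated
arch.  Its regional morphometry is summarised by dividing the shape into
100 radial segments with 99 "percentile" slices placed at equal
arc-length fractions along the callosal axis, and measuring the width of
each slice (the Denenberg centile technique).  This module implements
that measurement for an arbitrary 2-D binary mask:

1. trace the outer contour of the mask (marching squares at level 0.5),
2. locate the anterior (rostral/genu-side) and posterior (splenial) tips
   from the longest geodesic path of the morphological skeleton,
3. split the contour into a dorsal and a ventral arc,
4. fit the centreline by fixed-point iteration: slice the shape with
   lines normal to the current centreline at the 99 interior arc-length
   fractions, then replace the centreline with the slice midpoints,
   until the midpoints move by less than ``tol_mm``.

Coordinates are physical millimetres: x grows anterior→posterior (image
left→right), y grows ventral→dorsal (image bottom→top).  Centile 1 is
the most anterior slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes, distance_transform_edt
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure
from skimage.morphology import skeletonize

from .errors import CCError, CCWarning

__all__ = [
    "MidsagittalMask",
    "ClosedContour",
    "ArcPair",
    "Centreline",
    "WidthProfile",
    "extract_contour",
    "find_endpoints",
    "split_arcs",
    "fit_centile_widths",
    "shape_summary",
    "extract_width_profile",
    "segment_areas",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MidsagittalMask:
    """Binary mid-sagittal raster with physical pixel spacing.

    ``grid`` is row-major with row 0 at the image top; ``spacing`` is the
    (row, column) pixel size in mm.
    """

    grid: np.ndarray
    spacing: tuple[float, float]

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise CCError("bad-mask", "mask grid must be 2-D")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise CCError("bad-spacing", "pixel spacing must be positive")


@dataclass
class ClosedContour:
    """Simple closed polygon in mm, counter-clockwise, vertices not repeated."""

    points: np.ndarray  # (n, 2) of (x_mm, y_mm)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 3:
            raise CCError("bad-contour", "closed contour needs >= 3 vertices")

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class ArcPair:
    """Dorsal and ventral boundary arcs, both oriented anterior→posterior."""

    dorsal: np.ndarray   # (m, 2)
    ventral: np.ndarray  # (k, 2)

    @property
    def anterior_tip(self) -> np.ndarray:
        return self.dorsal[0]

    @property
    def posterior_tip(self) -> np.ndarray:
        return self.dorsal[-1]


@dataclass
class Centreline:
    """Ordered polyline from anterior to posterior tip."""

    points: np.ndarray  # (m, 2)

    @property
    def arc_length(self) -> np.ndarray:
        d = np.diff(self.points, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])


@dataclass
class WidthProfile:
    """99 centile widths plus the global geometric measures of one shape."""

    widths: np.ndarray            # (99,) mm, centile 1..99 anterior→posterior
    area: float                   # mm^2 (shoelace of the contour)
    perimeter: float              # mm
    centreline_length: float      # mm, tip-to-tip through the 99 midpoints
    n_segments: int = 100
    iterations: int = 0
    final_displacement: float = np.nan   # mm, last max midpoint move
    converged: bool = True
    displacement_history: list = field(default_factory=list)
    # slice endpoints kept for QC / segment-area accounting
    dorsal_points: np.ndarray | None = None   # (99, 2)
    ventral_points: np.ndarray | None = None  # (99, 2)

    def __post_init__(self):
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.shape != (99,):
            raise CCError("bad-profile", "expected exactly 99 widths")


# ---------------------------------------------------------------------------
# contour extraction
# ---------------------------------------------------------------------------

def extract_contour(mask: MidsagittalMask) -> ClosedContour:
    """Outer boundary of the largest 8-connected component, in mm.

    Marching squares at level 0.5, so a bar that is ``w`` pixels wide has
    geometric width ``w * spacing``.  Holes are filled and secondary
    components dropped, with a warning each.  A foreground region touching
    the raster border cannot be traced and raises ``mask-truncated``.
    """
    grid = mask.grid
    if not grid.any():
        raise CCError("empty-mask", "mask has no foreground pixels")

    labels, n_comp = measure.label(grid, connectivity=2, return_num=True)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        warnings.warn(
            f"mask has {n_comp} components; keeping the largest "
            f"({sizes[keep - 1]} px)", CCWarning)
        grid = labels == keep
    filled = binary_fill_holes(grid)
    if filled.sum() != grid.sum():
        warnings.warn("mask holes were filled", CCWarning)
        grid = filled

    if grid[0, :].any() or grid[-1, :].any() or grid[:, 0].any() or grid[:, -1].any():
        raise CCError("mask-truncated", "foreground touches the image border")

    contours = measure.find_contours(grid.astype(float), level=0.5)
    ring = max(contours, key=len)  # (row, col), closed (first == last)
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    h = grid.shape[0]
    row_mm, col_mm = mask.spacing
    pts = np.column_stack([ring[:, 1] * col_mm, (h - 1 - ring[:, 0]) * row_mm])
    contour = ClosedContour(pts)
    if contour.signed_area < 0:
        contour = ClosedContour(pts[::-1])
    return contour


def shape_summary(contour: ClosedContour) -> tuple[float, float]:
    """(shoelace area mm^2, perimeter mm) of a simple closed polygon."""
    return contour.area, contour.perimeter


# ---------------------------------------------------------------------------
# endpoint detection (skeleton longest geodesic path)
# ---------------------------------------------------------------------------

def _skeleton_diameter_path(grid: np.ndarray, spacing: tuple[float, float]):
    """Longest geodesic path of the morphological skeleton, in mm.

    Double-sweep Dijkstra: farthest point from an arbitrary start, then
    farthest from that — exact on trees, a standard heuristic otherwise.
    Returns (path points (m, 2) in mm ordered end to end, length_mm).
    """
    skel = skeletonize(grid)
    coords = np.argwhere(skel)
    if len(coords) == 0:
        raise CCError("no-elongation", "skeleton is empty")
    idx = -np.ones(grid.shape, dtype=int)
    idx[coords[:, 0], coords[:, 1]] = np.arange(len(coords))

    row_mm, col_mm = spacing
    rows_i, cols_i, wts = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r2, c2 = coords[:, 0] + dr, coords[:, 1] + dc
        ok = (r2 >= 0) & (r2 < grid.shape[0]) & (c2 >= 0) & (c2 < grid.shape[1])
        ok[ok] &= skel[r2[ok], c2[ok]]
        a = idx[coords[ok, 0], coords[ok, 1]]
        b = idx[r2[ok], c2[ok]]
        w = np.full(len(a), np.hypot(dr * row_mm, dc * col_mm))
        rows_i.append(a); cols_i.append(b); wts.append(w)
    n = len(coords)
    if sum(len(r) for r in rows_i) == 0:
        return None  # single-pixel skeleton
    adj = coo_matrix((np.concatenate(wts),
                      (np.concatenate(rows_i), np.concatenate(cols_i))),
                     shape=(n, n))
    adj = adj + adj.T

    d0 = dijkstra(adj, indices=0, directed=False)
    d0[np.isinf(d0)] = -1.0
    a = int(np.argmax(d0))
    da, pred = dijkstra(adj, indices=a, directed=False,
                        return_predecessors=True)
    da[np.isinf(da)] = -1.0
    b = int(np.argmax(da))
    length = float(da[b])
    path = [b]
    while path[-1] != a:
        path.append(int(pred[path[-1]]))

    h = grid.shape[0]
    pts = coords[np.asarray(path)]
    path_mm = np.column_stack([pts[:, 1] * col_mm, (h - 1 - pts[:, 0]) * row_mm])
    return path_mm, length


def _fit_circle(pts: np.ndarray):
    """Kasa least-squares circle fit; returns (center, radius) or None."""
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    try:
        sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return None
    if rank < 3:
        return None
    c = sol[:2]
    r = float(np.sqrt(max(sol[2] + c @ c, 0.0)))
    if not np.isfinite(r) or r > 1e5:
        return None
    return c, r


def _axis_tip(path_mm: np.ndarray, dt_mm: np.ndarray, grid: np.ndarray,
              spacing: tuple[float, float], end: int) -> np.ndarray:
    """Extrapolate one end of the skeleton path to the shape boundary.

    Skeletons of blunt-ended shapes terminate in corner spurs, so the
    raw path end is unreliable.  The path is trimmed from the chosen end
    until its arc length exceeds twice the local half-width (distance
    transform), i.e. until it is clear of the spur region; a circle is
    fitted to the next ~10 mm of path (a straight line when the fit
    degenerates) and followed outward in small steps until it leaves the
    foreground.  Following the curve rather than a straight ray keeps
    the tip on the axis of curved shapes.
    """
    pts = path_mm if end == 0 else path_mm[::-1]
    dt = dt_mm if end == 0 else dt_mm[::-1]
    seg = np.hypot(*np.diff(pts, axis=0).T)
    L = np.concatenate([[0.0], np.cumsum(seg)])
    past = np.where(L >= 2.0 * dt)[0]
    i = int(past[0]) if len(past) else 0
    i = min(i, len(pts) // 3)  # never trim away most of the path
    j = int(np.searchsorted(L, L[i] + 10.0))
    j = min(max(j, i + 4), len(pts) - 1)
    region = pts[i:j + 1]
    start = pts[i]
    u = start - pts[j]
    norm = np.hypot(*u)
    if norm == 0:
        return pts[0]
    u = u / norm

    h = grid.shape[0]
    row_mm, col_mm = spacing

    def inside(q):
        r = int(round(h - 1 - q[1] / row_mm))
        c = int(round(q[0] / col_mm))
        return 0 <= r < h and 0 <= c < grid.shape[1] and grid[r, c]

    fit = _fit_circle(region) if len(region) >= 5 else None
    max_walk = float(L[i] + 3.0 * dt[i] + 5.0)
    step = 0.25 * min(row_mm, col_mm)
    q_prev = start
    s = step
    while s <= max_walk:
        if fit is None:
            q = start + s * u
        else:
            c, r = fit
            theta0 = np.arctan2(start[1] - c[1], start[0] - c[0])
            # angular direction matching the outward tangent u
            tang = np.array([-np.sin(theta0), np.cos(theta0)])
            sign = 1.0 if tang @ u > 0 else -1.0
            th = theta0 + sign * s / r
            q = c + r * np.array([np.cos(th), np.sin(th)])
        if not inside(q):
            return 0.5 * (q_prev + q)
        q_prev = q
        s += step
    return pts[0]


def find_endpoints(
    contour: ClosedContour,
    mask: MidsagittalMask | None = None,
    hint: tuple | None = None,
) -> tuple[int, int]:
    """Indices of the anterior and posterior tip vertices on the contour.

    Default: the contour vertices nearest the two ends of the skeleton's
    longest geodesic path; with ``hint`` = ((x, y), (x, y)) in mm, the
    nearest contour vertices to the hinted points instead.  Anterior is
    the endpoint with smaller x (ties broken toward smaller y).
    """
    pts = contour.points
    if hint is not None:
        targets = [np.asarray(h, dtype=float) for h in hint]
    else:
        if mask is None:
            raise CCError("no-elongation", "skeleton endpoints need the mask")
        res = _skeleton_diameter_path(mask.grid, mask.spacing)
        if res is None:
            raise CCError("no-elongation", "skeleton degenerate; provide a hint")
        path_mm, length = res
        # near-circular blobs have no meaningful axis
        equiv_diam = 2.0 * np.sqrt(contour.area / np.pi)
        if length < 1.2 * equiv_diam:
            raise CCError(
                "no-elongation",
                f"skeleton path {length:.1f} mm vs equivalent diameter "
                f"{equiv_diam:.1f} mm; provide an endpoint hint")
        dt = distance_transform_edt(mask.grid, sampling=mask.spacing)
        h = mask.grid.shape[0]
        row_mm, col_mm = mask.spacing
        rows = (h - 1 - path_mm[:, 1] / row_mm).round().astype(int)
        cols = (path_mm[:, 0] / col_mm).round().astype(int)
        dt_mm = dt[rows, cols]
        targets = [_axis_tip(path_mm, dt_mm, mask.grid, mask.spacing, end)
                   for end in (0, 1)]

    ia = int(np.argmin(np.hypot(*(pts - targets[0]).T)))
    ib = int(np.argmin(np.hypot(*(pts - targets[1]).T)))
    if ia == ib:
        raise CCError("degenerate-cut", "endpoints coincide")
    # anterior = smaller x; fall back to smaller y when x nearly equal
    span = np.ptp(pts, axis=0).max()
    if abs(pts[ia, 0] - pts[ib, 0]) > 0.05 * span:
        first = pts[ia, 0] < pts[ib, 0]
    else:
        first = pts[ia, 1] < pts[ib, 1]
    return (ia, ib) if first else (ib, ia)


def split_arcs(contour: ClosedContour, endpoints: tuple[int, int]) -> ArcPair:
    """Cut the closed contour at the two tips into dorsal and ventral arcs.

    Both arcs are returned oriented anterior→posterior; dorsal is the arc
    with the higher mean y.  The result is invariant to the stored
    orientation of the contour.
    """
    ia, ib = endpoints
    n = len(contour.points)
    if ia == ib or (abs(ia - ib) in (1, n - 1)):
        raise CCError("degenerate-cut", "cut points identical or adjacent")
    pts = contour.points
    if ia < ib:
        arc1 = pts[ia:ib + 1]
        arc2 = np.vstack([pts[ib:], pts[:ia + 1]])
    else:
        arc1 = np.vstack([pts[ia:], pts[:ib + 1]])
        arc2 = pts[ib:ia + 1]
    arc2 = arc2[::-1]  # both now run anterior tip -> posterior tip
    if np.mean(arc1[:, 1]) >= np.mean(arc2[:, 1]):
        dorsal, ventral = arc1, arc2
    else:
        dorsal, ventral = arc2, arc1
    return ArcPair(dorsal=np.array(dorsal), ventral=np.array(ventral))


# ---------------------------------------------------------------------------
# centile width fitting
# ---------------------------------------------------------------------------

def _resample(poly: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Points at the given arc-length fractions of a polyline."""
    d = np.diff(poly, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])
    t = fractions * s[-1]
    return np.column_stack([np.interp(t, s, poly[:, 0]),
                            np.interp(t, s, poly[:, 1])])


def _line_arc_intersections(p: np.ndarray, nvec: np.ndarray, arc: np.ndarray,
                            prev: np.ndarray | None,
                            positive_only: bool = False):
    """Signed distances t along the normal where line p + t*n meets the arc.

    Returns the t of the intersection nearest p (smallest positive t
    when ``positive_only``); near-ties (< 1e-9 mm) are broken toward the
    previous iteration's slice endpoint.
    """
    s0 = arc[:-1]
    d = np.diff(arc, axis=0)
    denom = nvec[0] * d[:, 1] - nvec[1] * d[:, 0]   # cross(n, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = s0 - p
        t = (rel[:, 0] * d[:, 1] - rel[:, 1] * d[:, 0]) / denom
        u = (rel[:, 0] * nvec[1] - rel[:, 1] * nvec[0]) / denom
    ok = (np.abs(denom) > 1e-12) & (u >= -1e-9) & (u <= 1 + 1e-9) & np.isfinite(t)
    if positive_only:
        ok &= t > 1e-9
    if not ok.any():
        return None
    ts = t[ok]
    best = np.abs(ts).min()
    cand = ts[np.abs(ts) <= best + 1e-9]
    if prev is not None and len(cand) > 1:
        pts = p + np.outer(cand, nvec)
        return float(cand[np.argmin(np.hypot(*(pts - prev).T))])
    return float(cand[np.argmin(np.abs(cand))])


def _smooth_chain(chain: np.ndarray, sigma: float = 3.0,
                  half: int = 6) -> np.ndarray:
    """Gaussian smoothing of a sampled chain for tangent estimation.

    Raster noise and the fixed tip vertices put high-frequency kinks in
    the midpoint chain; tangents from the raw chain tilt the slices and
    destabilize the iteration.  The end points are pinned.
    """
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    k /= k.sum()
    pad = np.vstack([chain[:1].repeat(half, 0), chain,
                     chain[-1:].repeat(half, 0)])
    # ends deliberately not pinned: a pinned tip vertex drags the local
    # tangent and destabilizes the first and last slice
    return np.column_stack([np.convolve(pad[:, 0], k, "valid"),
                            np.convolve(pad[:, 1], k, "valid")])


def fit_centile_widths(
    arcs: ArcPair,
    n_segments: int = 100,
    tol_mm: float = 0.01,
    max_iter: int = 100,
    contour: ClosedContour | None = None,
    relax: float = 0.5,
    anneal: float = 0.93,
) -> tuple[WidthProfile, Centreline]:
    """Iterative percentile-slice width measurement.

    The centreline starts as the pointwise mean of the two arcs resampled
    at matched arc-length fractions.  Each iteration resamples it at the
    interior fractions k/n_segments, slices the shape with the local
    normals, and moves the interior points toward the slice midpoints
    (tips fixed, under-relaxation factor ``relax``), until the maximum
    midpoint displacement drops below ``tol_mm``.  Widths are the
    dorsal–ventral slice lengths of the final iteration.
    """
    if n_segments < 2:
        raise CCError("bad-config", "n_segments must be >= 2")
    fr_all = np.arange(n_segments + 1) / n_segments
    interior = slice(1, n_segments)

    dor = _resample(arcs.dorsal, fr_all)
    ven = _resample(arcs.ventral, fr_all)
    chain = 0.5 * (dor + ven)
    chain[0] = arcs.anterior_tip
    chain[-1] = arcs.posterior_tip

    prev_d = prev_v = None
    history: list[float] = []
    converged = False
    widths = dpts = vpts = None
    it = 0
    for it in range(1, max_iter + 1):
        samp = _resample(chain, fr_all)
        # central-difference tangents on the smoothed chain
        sm = _smooth_chain(samp)
        tang = sm[2:] - sm[:-2]
        tang /= np.hypot(tang[:, 0], tang[:, 1])[:, None]
        normals = np.column_stack([-tang[:, 1], tang[:, 0]])
        pts = samp[interior]

        td = np.empty(n_segments - 1)
        tv = np.empty(n_segments - 1)
        for k in range(n_segments - 1):
            a = _line_arc_intersections(
                pts[k], normals[k], arcs.dorsal,
                None if prev_d is None else prev_d[k])
            b = _line_arc_intersections(
                pts[k], normals[k], arcs.ventral,
                None if prev_v is None else prev_v[k])
            if a is None or b is None:
                raise CCError("slice-miss",
                              f"normal slice missed an arc at centile {k + 1}")
            td[k], tv[k] = a, b
        dpts = pts + td[:, None] * normals
        vpts = pts + tv[:, None] * normals
        widths = np.abs(td - tv)
        mids = 0.5 * (dpts + vpts)
        # annealed under-relaxation: damps the limit cycle the raw
        # midpoint map can enter beside blunt tips, where the slice is
        # geometrically ill-posed; interior stations equilibrate within
        # the first few iterations, before the step size has decayed
        newpts = pts + relax * anneal ** (it - 1) * (mids - pts)
        disp = float(np.hypot(*(newpts - pts).T).max())
        history.append(disp)
        chain = np.vstack([chain[:1], newpts, chain[-1:]])
        prev_d, prev_v = dpts, vpts
        if disp < tol_mm:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"centreline did not converge in {max_iter} iterations "
            f"(last displacement {history[-1]:.4g} mm)", CCWarning)

    centreline = Centreline(points=chain)
    if contour is not None:
        area, perim = shape_summary(contour)
    else:
        ring = np.vstack([arcs.dorsal, arcs.ventral[::-1]])
        c = ClosedContour(ring)
        area, perim = c.area, c.perimeter
    profile = WidthProfile(
        widths=widths, area=area, perimeter=perim,
        centreline_length=centreline.length, n_segments=n_segments,
        iterations=it, final_displacement=history[-1], converged=converged,
        displacement_history=history, dorsal_points=dpts, ventral_points=vpts)
    return profile, centreline


def segment_areas(profile: WidthProfile, centreline: Centreline) -> np.ndarray:
    """Areas of the 100 radial segments bounded by consecutive slices.

    End pieces are the triangles tip–first/last slice; interior pieces are
    the quadrilaterals between consecutive slices.  Their sum approximates
    the contour area (the arc between slice endpoints is taken as a chord).
    """
    d, v = profile.dorsal_points, profile.ventral_points
    if d is None or v is None:
        raise CCError("bad-profile", "profile lacks slice endpoints")
    tip_a, tip_p = centreline.points[0], centreline.points[-1]

    def quad_area(q):
        x, y = q[:, 0], q[:, 1]
        return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    areas = [quad_area(np.array([tip_a, d[0], v[0]]))]
    for k in range(len(d) - 1):
        areas.append(quad_area(np.array([d[k], d[k + 1], v[k + 1], v[k]])))
    areas.append(quad_area(np.array([d[-1], tip_p, v[-1]])))
    return np.asarray(areas)


def extract_width_profile(
    mask: MidsagittalMask,
    hint: tuple | None = None,
    n_segments: int = 100,
    tol_mm: float = 0.01,
    max_iter: int = 100,
) -> tuple[WidthProfile, Centreline]:
    """Mask → width profile, running the full geometric chain.

    The mask is first brought to a canonical left-right orientation (a
    deterministic lexicographic rule on the raster), so that a mirrored
    mask yields the exactly reversed width vector: skeletonization is
    not mirror-covariant pixel for pixel, and without canonicalization
    the tip placement — hence the widths near the tips — would drift by
    a pixel between a mask and its mirror image.
    """
    grid = mask.grid
    mirrored = grid[:, ::-1]
    flip = mirrored.tobytes() < grid.tobytes()
    if flip:
        width_mm = (grid.shape[1] - 1) * mask.spacing[1]
        mask = MidsagittalMask(mirrored.copy(), mask.spacing)
        if hint is not None:
            hint = tuple((width_mm - h[0], h[1]) for h in hint)

    contour = extract_contour(mask)
    ends = find_endpoints(contour, mask=mask, hint=hint)
    arcs = split_arcs(contour, ends)
    profile, centreline = fit_centile_widths(
        arcs, n_segments=n_segments, tol_mm=tol_mm, max_iter=max_iter,
        contour=contour)

    if flip:
        def unflip(p):
            q = p.copy()
            q[:, 0] = width_mm - q[:, 0]
            return q[::-1]
        profile.widths = profile.widths[::-1].copy()
        profile.dorsal_points = unflip(profile.dorsal_points)
        profile.ventral_points = unflip(profile.ventral_points)
        centreline = Centreline(points=unflip(centreline.points))
    return profile, centreline
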