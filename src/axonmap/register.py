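"""Cycle-to-cycle alignment and tile stitching in dot space.

Alignment is rigid-to-projective, never non-linear.  Point clouds are first
coarsely aligned by phase correlation of their rasterized density images,
then refined by nearest-neighbour pairing within a distance gate and a
least-squares affine (or projective) fit, iterated to convergence of the
RMS residual.  Cycles are aligned to mid-sequencing reference cycles;
tiles are stitched in descending rolony-count order, each new tile
registered against the union of already-placed neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class Transform2D:
    """Homogeneous 2-D transform with registration diagnostics."""

    kind: str  # translation | affine | projective
    matrix: np.ndarray  # 3×3 homogeneous
    rms_residual: float = 0.0
    n_support: int = 0
    low_confidence: bool = False

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        h = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return h[:, :2] / h[:, 2:3]

    def compose(self, other: "Transform2D") -> "Transform2D":
        """Transform equal to applying ``other`` first, then ``self``."""
        kinds = ["translation", "affine", "projective"]
        kind = kinds[max(kinds.index(self.kind), kinds.index(other.kind))]
        return Transform2D(kind=kind, matrix=self.matrix @ other.matrix)

    def inverse(self) -> "Transform2D":
        return Transform2D(kind=self.kind, matrix=np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls, kind: str = "translation") -> "Transform2D":
        return cls(kind=kind, matrix=np.eye(3))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "Transform2D":
        m = np.eye(3)
        m[0, 2], m[1, 2] = dx, dy
        return cls(kind="translation", matrix=m)


def rasterize(points: np.ndarray, bin_size: float = 1.0,
              bounds: tuple[float, float, float, float] | None = None) -> tuple[np.ndarray, tuple[float, float]]:
    """Bin a point cloud into a 2-D count image; returns (image, origin)."""
    points = np.asarray(points, dtype=float)
    if bounds is None:
        x0, y0 = points.min(axis=0) - bin_size
        x1, y1 = points.max(axis=0) + bin_size
    else:
        x0, y0, x1, y1 = bounds
    nx = max(int(np.ceil((x1 - x0) / bin_size)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_size)), 1)
    ix = np.clip(((points[:, 0] - x0) / bin_size).astype(int), 0, nx - 1)
    iy = np.clip(((points[:, 1] - y0) / bin_size).astype(int), 0, ny - 1)
    img = np.zeros((ny, nx))
    np.add.at(img, (iy, ix), 1.0)
    return img, (x0, y0)


def _phase_correlate(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Shift (dx, dy) moving ``b`` onto ``a`` via the normalized cross-power
    spectrum, refined to subpixel by parabolic peak interpolation.
    Returns (dx, dy, confidence)."""
    shape = (max(a.shape[0], b.shape[0]), max(a.shape[1], b.shape[1]))
    Fa = np.fft.rfft2(a, s=shape)
    Fb = np.fft.rfft2(b, s=shape)
    R = Fa * np.conj(Fb)
    mag = np.abs(R)
    R = np.where(mag > 0, R / np.maximum(mag, 1e-12), 0)
    corr = np.fft.irfft2(R, s=shape)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    pval = corr[peak]
    # confidence: peak height relative to the correlation-surface noise
    sd = corr.std()
    confidence = float(pval / sd) if sd > 0 else 0.0

    def wrap(i: int, n: int) -> float:
        return float(i - n) if i > n // 2 else float(i)

    dy, dx = wrap(peak[0], shape[0]), wrap(peak[1], shape[1])

    def para(m1: float, c0: float, p1: float) -> float:
        den = m1 - 2 * c0 + p1
        return float(np.clip(0.5 * (m1 - p1) / den, -0.5, 0.5)) if den < 0 else 0.0

    dy += para(corr[(peak[0] - 1) % shape[0], peak[1]], pval,
               corr[(peak[0] + 1) % shape[0], peak[1]])
    dx += para(corr[peak[0], (peak[1] - 1) % shape[1]], pval,
               corr[peak[0], (peak[1] + 1) % shape[1]])
    return dx, dy, confidence


def prealign_translation(
    a, b, bin_size: float = 1.0, confidence_floor: float = 5.0
) -> Transform2D:
    """Translation aligning ``b`` onto ``a`` by phase correlation.

    Inputs are either 2-D images or (n, 2) point clouds (rasterized at
    ``bin_size``).  A correlation peak below ``confidence_floor`` standard
    deviations of the correlation surface flags the transform low-confidence.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    is_cloud = a.ndim == 2 and a.shape[1] == 2 and b.ndim == 2 and b.shape[1] == 2 \
        and not (a.shape[0] == a.shape[1] == 2 and np.allclose(a, b))
    if is_cloud:
        pts = np.vstack([a, b])
        x0, y0 = pts.min(axis=0) - bin_size
        x1, y1 = pts.max(axis=0) + bin_size
        img_a, _ = rasterize(a, bin_size, (x0, y0, x1, y1))
        img_b, _ = rasterize(b, bin_size, (x0, y0, x1, y1))
        dx, dy, _ = _phase_correlate(img_a, img_b)
        dx, dy = dx * bin_size, dy * bin_size
        # confidence from actual point support after the shift
        shifted = b + [dx, dy]
        d, _ = cKDTree(a).query(shifted, distance_upper_bound=2 * bin_size)
        support = np.isfinite(d).mean()
        low = support < 0.5  # less than half the dots land on a partner
    else:
        dx, dy, conf = _phase_correlate(a, b)
        low = conf < confidence_floor
    t = Transform2D.translation(dx, dy)
    t.low_confidence = bool(low)
    return t


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    A = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
    m = np.eye(3)
    m[:2] = coef.T
    return m


def _fit_projective(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    # direct linear transform, normalized
    n = len(src)
    A = np.zeros((2 * n, 9))
    for i, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        A[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y, -u]
        A[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y, -v]
    _, _, Vt = np.linalg.svd(A)
    H = Vt[-1].reshape(3, 3)
    return H / H[2, 2]


class RegistrationError(RuntimeError):
    def __init__(self, msg: str, n_support: int = 0):
        super().__init__(msg)
        self.n_support = n_support


def register_point_clouds(
    src: np.ndarray,
    ref: np.ndarray,
    kind: str = "affine",
    gate: float = 5.0,
    bin_size: float = 1.0,
    tol: float = 0.01,
    max_iter: int = 20,
    min_points: int = 10,
    min_pairs: int = 4,
    projective_min_support: int = 50,
) -> Transform2D:
    """Register ``src`` dots onto ``ref`` dots.

    Coarse translation by rasterized phase correlation, then iterated
    nearest-neighbour pairing within ``gate`` pixels and least-squares
    model fitting until the RMS residual changes by less than ``tol`` px.
    ``kind='projective'`` falls back to affine below
    ``projective_min_support`` matched pairs.
    """
    src = np.asarray(src, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if len(src) < min_points or len(ref) < min_points:
        raise RegistrationError(
            f"need >= {min_points} points, got {len(src)}/{len(ref)}",
            n_support=min(len(src), len(ref)),
        )
    t = prealign_translation(ref, src, bin_size=bin_size)
    matrix = t.matrix
    tree = cKDTree(ref)
    prev_rms = np.inf
    rms = np.inf
    n_support = 0
    for _ in range(max_iter):
        warped = Transform2D(kind="affine", matrix=matrix).apply(src)
        dist, idx = tree.query(warped, distance_upper_bound=gate)
        ok = np.isfinite(dist)
        n_support = int(ok.sum())
        if n_support < min_pairs:
            raise RegistrationError("insufficient pairs after gating", n_support)
        s, d = src[ok], ref[idx[ok]]
        use_projective = kind == "projective" and n_support >= projective_min_support
        matrix = _fit_projective(s, d) if use_projective else _fit_affine(s, d)
        warped = Transform2D(kind="affine", matrix=matrix).apply(src)
        rms = float(np.sqrt(np.mean(np.sum((warped[ok] - d) ** 2, axis=1))))
        if abs(prev_rms - rms) < tol:
            break
        prev_rms = rms
    out_kind = "projective" if (kind == "projective" and n_support >= projective_min_support) else "affine"
    return Transform2D(kind=out_kind, matrix=matrix, rms_residual=rms, n_support=n_support)


def align_cycles_to_reference(
    dots_by_cycle: dict[int, np.ndarray],
    reference_cycle: int | None = None,
    kind: str = "affine",
    gate: float = 5.0,
) -> dict[int, Transform2D]:
    """Composite transform per cycle into the reference-cycle frame.

    The reference defaults to the middle cycle (tissue distortion grows
    with cycle number, so a mid-sequencing reference halves the worst-case
    drift).  Each cycle is registered directly to the reference; a failing
    cycle keeps its phase-correlation prealignment, flagged low-confidence.
    """
    cycles = sorted(dots_by_cycle)
    if reference_cycle is None:
        reference_cycle = cycles[len(cycles) // 2]
    if reference_cycle not in dots_by_cycle:
        raise ValueError("reference cycle absent from input")
    ref = np.asarray(dots_by_cycle[reference_cycle], dtype=float)
    chains: dict[int, Transform2D] = {}
    for c in cycles:
        if c == reference_cycle:
            chains[c] = Transform2D.identity(kind)
            continue
        pts = np.asarray(dots_by_cycle[c], dtype=float)
        try:
            chains[c] = register_point_clouds(pts, ref, kind=kind, gate=gate)
        except RegistrationError:
            if len(pts) and len(ref):
                t = prealign_translation(ref, pts)
            else:
                t = Transform2D.identity()
            t.low_confidence = True
            chains[c] = t
    return chains


def apply_transforms(dots: pd.DataFrame, chains: dict[int, Transform2D]) -> pd.DataFrame:
    """Map per-cycle dot coordinates into the reference frame."""
    out = dots.copy()
    for c, t in chains.items():
        sel = out["cycle"] == c
        if sel.any():
            out.loc[sel, ["x", "y"]] = t.apply(out.loc[sel, ["x", "y"]].to_numpy())
    return out


def stitch_tiles(
    dots_by_tile: dict[int, np.ndarray],
    layout: dict[int, tuple[float, float]],
    neighbor_overlap: float | None = None,
    bin_size: float = 1.0,
) -> tuple[dict[int, Transform2D], list[list[int]]]:
    """Place tiles into a shared section frame.

    ``layout`` gives the nominal (x, y) offset of each tile (from imaging
    positions, 15% overlap typical).  Tiles are placed in descending
    rolony-count order; each subsequent tile is refined by phase
    correlation of its dot raster against the union of already-placed
    dots.  Returns per-tile transforms and the connected components of the
    tile adjacency graph (components are stitched independently when the
    graph is disconnected, with a warning).
    """
    import warnings

    order = sorted(dots_by_tile, key=lambda t: -len(dots_by_tile[t]))
    transforms: dict[int, Transform2D] = {}
    placed_pts: list[np.ndarray] = []
    components: list[list[int]] = []

    def nominal(tile: int) -> Transform2D:
        return Transform2D.translation(*layout[tile])

    for tile in order:
        t0 = nominal(tile)
        pts = t0.apply(np.asarray(dots_by_tile[tile], dtype=float))
        if not placed_pts:
            transforms[tile] = t0
            placed_pts.append(pts)
            components.append([tile])
            continue
        union = np.vstack(placed_pts)
        # restrict to the neighbourhood of this tile to keep rasters small
        lo, hi = pts.min(axis=0) - 50, pts.max(axis=0) + 50
        near = union[np.all((union >= lo) & (union <= hi), axis=1)]
        if len(near) < 3:
            warnings.warn(f"tile {tile} shares no overlap; stitched by nominal offset",
                          stacklevel=2)
            transforms[tile] = t0
            placed_pts.append(pts)
            components.append([tile])
            continue
        refine = prealign_translation(near, pts, bin_size=bin_size)
        t = refine.compose(t0)
        # subpixel polish: mean offset of gated duplicate pairs
        tree = cKDTree(near)
        cur = t.apply(np.asarray(dots_by_tile[tile], dtype=float))
        for _ in range(3):
            d, idx = tree.query(cur, distance_upper_bound=3 * bin_size)
            ok = np.isfinite(d)
            if ok.sum() < 3:
                break
            delta = (near[idx[ok]] - cur[ok]).mean(axis=0)
            t = Transform2D.translation(*delta).compose(t)
            cur = cur + delta
            if np.hypot(*delta) < 1e-3:
                break
        transforms[tile] = t
        placed_pts.append(t.apply(np.asarray(dots_by_tile[tile], dtype=float)))
        components[0].append(tile)
    return transforms, components


def apply_displacement_field(
    points: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    field: np.ndarray,
) -> np.ndarray:
    """Apply a user-supplied sampled displacement field to points.

    ``field`` has shape (ny, nx, 2) giving (dx, dy) at the grid nodes
    ``grid_x`` × ``grid_y``; displacements are interpolated linearly at the
    point locations and added.  Fitting such fields (e.g. from manual
    control points) is outside the scope of this package.
    """
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (grid_y, grid_x), field, bounds_error=False, fill_value=0.0
    )
    pts = np.asarray(points, dtype=float)
    disp = interp(pts[:, ::-1])
    return pts + disp


def serialize_transforms(chains: dict[int, Transform2D], path) -> None:
    """Write transform chains as structured text (row-major 3×3)."""
    with open(path, "w") as fh:
        for c in sorted(chains):
            t = chains[c]
            row = " ".join(f"{v:.10g}" for v in t.matrix.ravel())
            fh.write(f"{c}\t{t.kind}\t{row}\t{t.rms_residual:.6g}\t{t.n_support}\n")


def load_transforms(path) -> dict[int, Transform2D]:
    chains = {}
    with open(path) as fh:
        for line in fh:
            key, kind, row, rms, n = line.rstrip("\n").split("\t")
            chains[int(key)] = Transform2D(
                kind=kind, matrix=np.array([float(v) for v in row.split()]).reshape(3, 3),
                rms_residual=float(rms), n_support=int(n),
            )
    return chains
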