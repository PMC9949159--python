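"""Single-neuron projection statistics on flatmap coordinates.

Laminar termination patterns are summarized per cell and target region as
depth histograms/CDFs (1% bins).  Two regions' patterns are compared with
a permutation Kolmogorov–Smirnov test: the KS distance between the two
binned CDFs, with a null built by shuffling the rolony depths across the
two regions within the cell (1000 shuffles); patterns are called
different at p <= 0.05.  Group-level fractions of "different" cells carry
percentile-bootstrap confidence intervals (2000 iterations, 2.5/97.5%).

Tangential projection shape is summarized by the *focal projection
distance*: per rolony, the mean of its shortest 33% of pairwise ML–AP
distances to the cell's other rolonies; per cell, the mean over rolonies.
The module also provides simulated retrograde tracing (select cells
projecting into a flatmap patch) and a single-cell reconstruction that
links rolonies and soma into a tree by nearest-neighbour cluster merging
with a 1000 μm edge cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

DEPTH_GRID = np.arange(0.0, 100.0 + 1e-9, 1.0)  # 1% bins


@dataclass
class LaminarProfile:
    """Depth histogram + CDF of one cell/region's rolonies."""

    histogram: np.ndarray  # sums to 1 for n > 0
    cdf: np.ndarray
    n_rolonies: int
    region: str = ""
    bin_width: float = 1.0

    @classmethod
    def from_depths(cls, depths: np.ndarray, region: str = "",
                    bin_width: float = 1.0) -> "LaminarProfile":
        edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
        h, _ = np.histogram(np.clip(depths, 0, 100 - 1e-9), bins=edges)
        n = len(depths)
        hist = h / n if n else h.astype(float)
        return cls(histogram=hist, cdf=np.cumsum(hist), n_rolonies=n,
                   region=region, bin_width=bin_width)


@dataclass
class InjectionMask:
    """Tangential exclusion disk around the injection site."""

    center: tuple[float, float]  # median soma (ML, AP)
    radius: float  # 95th percentile of soma distances to the center
    mirrored_center: tuple[float, float] | None = None  # local-exclusion control

    @classmethod
    def from_somata(cls, soma_ml_ap: np.ndarray, percentile: float = 95.0,
                    mirrored_center: tuple[float, float] | None = None) -> "InjectionMask":
        soma_ml_ap = np.asarray(soma_ml_ap, float)
        center = np.median(soma_ml_ap, axis=0)
        d = np.linalg.norm(soma_ml_ap - center, axis=1)
        return cls(center=tuple(center), radius=float(np.percentile(d, percentile)),
                   mirrored_center=mirrored_center)


def cortical_rolony_prep(
    rolonies: pd.DataFrame,
    mask: InjectionMask | None = None,
    max_depth: float = 95.0,
) -> pd.DataFrame:
    """Analysis-ready cortical rolonies.

    Drops rolonies deeper than ``max_depth``% (proximity to the fiber
    tract makes those registration-fragile) and rolonies inside the
    injection disk (and its mirrored contralateral control disk when
    configured).  Requires columns ml, ap, depth.
    """
    out = rolonies[rolonies["depth"] <= max_depth]
    if mask is not None:
        d = np.hypot(out["ml"] - mask.center[0], out["ap"] - mask.center[1])
        keep = d > mask.radius
        if mask.mirrored_center is not None:
            dm = np.hypot(out["ml"] - mask.mirrored_center[0],
                          out["ap"] - mask.mirrored_center[1])
            keep &= dm > mask.radius
        out = out[keep]
    return out.reset_index(drop=True)


def _binned_cdf(depths: np.ndarray, nbins: int = 100) -> np.ndarray:
    idx = np.clip(depths.astype(int), 0, nbins - 1)
    h = np.bincount(idx, minlength=nbins)
    return np.cumsum(h) / len(depths)


def ks_permutation(
    depths_a: np.ndarray,
    depths_b: np.ndarray,
    n_shuffles: int = 1000,
    rng: np.random.Generator | int | None = None,
    plus_one: bool = False,
) -> tuple[float, float]:
    """Permutation KS test between two depth samples on the 1% grid.

    KS = max |CDF_A − CDF_B| over the 100 depth bins; p = fraction of
    label-shuffled KS distances >= the observed one.  ``plus_one`` enables
    the (b+1)/(M+1) estimator; the plain fraction is the default.  Empty
    samples return (nan, nan).
    """
    a = np.asarray(depths_a, float)
    b = np.asarray(depths_b, float)
    if len(a) == 0 or len(b) == 0:
        return float("nan"), float("nan")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nbins = 100
    ai = np.clip(a, 0, nbins - 1e-9).astype(int)
    bi = np.clip(b, 0, nbins - 1e-9).astype(int)
    obs = float(np.abs(np.cumsum(np.bincount(ai, minlength=nbins)) / len(a)
                       - np.cumsum(np.bincount(bi, minlength=nbins)) / len(b)).max())
    pool = np.concatenate([ai, bi])
    n, na = len(pool), len(a)
    perm = np.argsort(rng.random((n_shuffles, n)), axis=1)
    shuffled = pool[perm]
    av, bv = shuffled[:, :na], shuffled[:, na:]
    offs = nbins * np.arange(n_shuffles)[:, None]
    ca = np.bincount((av + offs).ravel(), minlength=n_shuffles * nbins)
    cb = np.bincount((bv + offs).ravel(), minlength=n_shuffles * nbins)
    cdf_a = np.cumsum(ca.reshape(n_shuffles, nbins), axis=1) / na
    cdf_b = np.cumsum(cb.reshape(n_shuffles, nbins), axis=1) / (n - na)
    ks_null = np.abs(cdf_a - cdf_b).max(axis=1)
    hits = int((ks_null >= obs - 1e-12).sum())
    p = (hits + 1) / (n_shuffles + 1) if plus_one else hits / n_shuffles
    return obs, float(p)


def fraction_different(
    p_values: np.ndarray,
    alpha: float = 0.05,
    n_bootstrap: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Percentage of cells whose two laminar patterns differ (p <= alpha),
    with a percentile-bootstrap 95% CI over cells.  A single cell gives a
    degenerate point interval."""
    p = np.asarray(p_values, float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        return float("nan"), (float("nan"), float("nan"))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    different = p <= alpha
    pct = 100.0 * different.mean()
    if len(p) == 1:
        import warnings

        warnings.warn("single cell: degenerate bootstrap interval", stacklevel=2)
        return pct, (pct, pct)
    idx = rng.integers(0, len(p), size=(n_bootstrap, len(p)))
    boots = 100.0 * different[idx].mean(axis=1)
    return pct, (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))


def soma_depth_groups(depths_pct: np.ndarray,
                      bounds: tuple[float, float] = (35.0, 60.0)) -> np.ndarray:
    """Group somata by depth: <= 35% upper, (35, 60]% middle, > 60% deep;
    unknown depth (NaN) is excluded (empty label)."""
    d = np.asarray(depths_pct, float)
    out = np.full(len(d), "", dtype=object)
    out[d <= bounds[0]] = "upper"
    out[(d > bounds[0]) & (d <= bounds[1])] = "middle"
    out[d > bounds[1]] = "deep"
    out[~np.isfinite(d)] = ""
    return out


def focal_distance(
    points_ml_ap: np.ndarray,
    fraction: float = 0.33,
    min_n: int = 55,
) -> float:
    """Focal projection distance of one cell on the ML–AP plane.

    Per rolony: mean of its shortest ``ceil(fraction × (n−1))`` distances
    to the other rolonies (self excluded); the cell value is the mean over
    rolonies.  Cells with fewer than ``min_n`` rolonies return NaN
    (excluded — subsampling error is too high below that count).
    """
    pts = np.asarray(points_ml_ap, float)
    n = len(pts)
    if n < min_n:
        return float("nan")
    k = int(np.ceil(fraction * (n - 1)))
    D = cdist(pts, pts)
    np.fill_diagonal(D, np.inf)
    part = np.partition(D, k - 1, axis=1)[:, :k]
    return float(part.mean())


def subsampling_error_curve(
    points_ml_ap: np.ndarray,
    sizes: list[int],
    reps: int = 100,
    fraction: float = 0.33,
    rng: np.random.Generator | int | None = None,
) -> dict[int, float]:
    """Median relative focal-distance error per subsample size.

    Error = |d_sample − d_truth| / d_truth × 100%, ground truth from all
    points; sizes exceeding n are skipped.
    """
    pts = np.asarray(points_ml_ap, float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    truth = focal_distance(pts, fraction=fraction, min_n=2)
    out: dict[int, float] = {}
    for size in sizes:
        if size > len(pts):
            continue
        errs = np.empty(reps)
        for r in range(reps):
            sub = pts[rng.choice(len(pts), size=size, replace=False)]
            d = focal_distance(sub, fraction=fraction, min_n=2)
            errs[r] = abs(d - truth) / truth * 100.0 if truth > 0 else 0.0
        out[size] = float(np.median(errs))
    return out


def simulated_retrograde(
    cells: pd.DataFrame,
    rolonies: pd.DataFrame,
    center_ml_ap: tuple[float, float],
    radius: float = 300.0,
    min_patch: int = 10,
    specificity_ratio: float = 0.75,
    contra_regions: tuple[str, ...] = ("AudC", "VisC"),
) -> pd.DataFrame:
    """In silico retrograde tracing from a flatmap patch.

    A cell is positive iff it is IT class, has a soma location, and has
    >= ``min_patch`` rolonies within ``radius`` μm of the patch center on
    the ML–AP plane.  For contralateral patches, a positive is *specific*
    iff patch count / contralateral-cortex count >= ``specificity_ratio``.
    ``cells`` needs columns cell_id, cell_class, has_soma; ``rolonies``
    needs cell_id, ml, ap, region.
    """
    d = np.hypot(rolonies["ml"] - center_ml_ap[0], rolonies["ap"] - center_ml_ap[1])
    in_patch = rolonies[d <= radius].groupby("cell_id").size()
    contra = rolonies[rolonies["region"].isin(contra_regions)].groupby("cell_id").size()
    rows = []
    for _, c in cells.iterrows():
        n_patch = int(in_patch.get(c["cell_id"], 0))
        positive = (
            str(c["cell_class"]).startswith("IT")
            and n_patch >= min_patch
            and bool(c["has_soma"])
        )
        if not positive:
            continue
        n_contra = int(contra.get(c["cell_id"], 0))
        specific = n_contra > 0 and (n_patch / n_contra) >= specificity_ratio
        rows.append((c["cell_id"], n_patch, n_contra, specific))
    return pd.DataFrame(rows, columns=["cell_id", "n_patch", "n_contra", "specific"])


def reconstruct(points: np.ndarray, max_edge: float = 1000.0) -> list[tuple[int, int]]:
    """Skeletonize one cell's point cloud (rolonies + soma) into a tree.

    Every point first connects to its nearest neighbour (when within
    ``max_edge`` μm), forming clusters; the closest pair of clusters (via
    their closest points) is then merged repeatedly until no pair is
    within the cap.  Clusters farther apart than ``max_edge`` stay
    separate components.  Returns the edge list (point index pairs).
    """
    pts = np.asarray(points, float)
    n = len(pts)
    if n == 0:
        raise ValueError("need at least one point")
    if n == 1:
        return []
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges: list[tuple[int, int]] = []
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=2)
    for i in range(n):
        j = int(idx[i, 1])
        if dist[i, 1] <= max_edge and find(i) != find(j):
            parent[find(i)] = find(j)
            edges.append((min(i, j), max(i, j)))
    # merge clusters by their closest point pair
    D = cdist(pts, pts)
    np.fill_diagonal(D, np.inf)
    while True:
        roots = np.array([find(i) for i in range(n)])
        labels = np.unique(roots)
        if len(labels) == 1:
            break
        best = (np.inf, -1, -1)
        for a in range(len(labels)):
            ia = np.nonzero(roots == labels[a])[0]
            for b in range(a + 1, len(labels)):
                ib = np.nonzero(roots == labels[b])[0]
                sub = D[np.ix_(ia, ib)]
                k = np.unravel_index(np.argmin(sub), sub.shape)
                if sub[k] < best[0]:
                    best = (float(sub[k]), int(ia[k[0]]), int(ib[k[1]]))
        if best[0] > max_edge:
            break
        _, i, j = best
        parent[find(i)] = find(j)
        edges.append((min(i, j), max(i, j)))
    return edges
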