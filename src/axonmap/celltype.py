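"""Projection-type assignment: CF vs IT, then ET vs CT, then ITi vs ITc.

Corticofugal (CF) cells project to the thalamus or midbrain; the remaining
intratelencephalic (IT) cells split into ITc (>= 5 contralateral-cortex
rolonies) and ITi.  Thalamus-projecting CF cells divide into
extratelencephalic (ET) and corticothalamic (CT) subtypes by the route
their axons take through the striatal-thalamic fiber region: CT axons run
in the dorsal bundle, ET in the ventral bundle.  Labels are seeded by a
y-median split of the rolonies inside a fiber ROI and refined by iterative
k-nearest-neighbour majority voting, alternating rolony-level and
cell-level assignment until convergence; a final pass propagates the
labels over all thalamic rolonies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from axonmap.qc import CellRecord, DEFAULT_REGION_MINIMUMS

logger = logging.getLogger(__name__)

CT, ET = "CT", "ET"


@dataclass(frozen=True)
class FiberROI:
    """Axis-aligned box (μm) containing the CT/ET fiber bundles, split
    along y: the dorsal (top, smaller-y) half seeds CT, the ventral half
    ET."""

    x: tuple[float, float] = (8250.0, 9000.0)
    y: tuple[float, float] = (3500.0, 5000.0)
    z: tuple[float, float] = (6750.0, 7500.0)

    def __post_init__(self) -> None:
        if any(lo >= hi for lo, hi in (self.x, self.y, self.z)):
            raise ValueError("FiberROI box must be nonempty")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        return (
            (pts[:, 0] >= self.x[0]) & (pts[:, 0] <= self.x[1])
            & (pts[:, 1] >= self.y[0]) & (pts[:, 1] <= self.y[1])
            & (pts[:, 2] >= self.z[0]) & (pts[:, 2] <= self.z[1])
        )


def classify_cf_it(
    cells: list[CellRecord],
    region_minimums: dict[str, int] | None = None,
    thalamus_regions: tuple[str, ...] = ("Thal",),
    midbrain_regions: tuple[str, ...] = ("SupCol",),
    contra_regions: tuple[str, ...] = ("AudC", "VisC"),
    min_contra: int = 5,
) -> list[str]:
    """Top-level class per cell: CF, ITc or ITi.

    CF iff thalamic or midbrain counts reach their per-region minimums;
    otherwise ITc iff >= ``min_contra`` contralateral-cortex rolonies,
    else ITi.
    """
    if region_minimums is None:
        region_minimums = DEFAULT_REGION_MINIMUMS
    labels = []
    for cell in cells:
        counts = cell.region_counts
        cf = any(
            counts.get(r, 0) >= region_minimums.get(r, 1) and counts.get(r, 0) > 0
            for r in (*thalamus_regions, *midbrain_regions)
        )
        if cf:
            labels.append("CF")
        elif sum(counts.get(r, 0) for r in contra_regions) >= min_contra:
            labels.append("ITc")
        else:
            labels.append("ITi")
    return labels


def seed_etct(points: np.ndarray, roi: FiberROI) -> np.ndarray:
    """Initial rolony labels from the y-median split inside the ROI.

    Returns an object array aligned with ``points``: 'CT' for ROI rolonies
    in the top (smaller-y, dorsal) half, 'ET' for the bottom half, None
    outside the ROI.
    """
    points = np.asarray(points, float)
    labels = np.full(len(points), None, dtype=object)
    inside = roi.contains(points)
    if not inside.any():
        warnings.warn("no rolonies inside the fiber ROI; empty seed", stacklevel=2)
        return labels
    y = points[inside, 1]
    med = np.median(y)
    labels[inside] = np.where(y <= med, CT, ET)
    if inside.sum() == 1:
        warnings.warn("single rolony in fiber ROI", stacklevel=2)
    return labels


def _mode_with_tiebreak(votes: list[str], previous: str | None) -> str:
    n_ct = votes.count(CT)
    n_et = votes.count(ET)
    if n_ct > n_et:
        return CT
    if n_et > n_ct:
        return ET
    return previous if previous is not None else CT


def iterate_knn(
    labels: np.ndarray,
    points: np.ndarray,
    cell_ids: np.ndarray,
    k: int = 10,
    max_iter: int = 100,
) -> tuple[np.ndarray, dict, int]:
    """Refine seeded rolony labels by iterative kNN majority voting.

    Alternates (a) each labeled rolony takes the most frequent label of
    its ``k`` nearest labeled neighbours, (b) each cell takes the most
    frequent label of its rolonies, and its rolonies inherit the cell
    label, until no label changes or ``max_iter`` is reached.  Only
    rolonies labeled by the seed are in scope.  Ties keep the previous
    label (CT when there is none).  Returns (rolony labels, cell labels,
    iterations used).
    """
    labels = np.array(labels, dtype=object)
    points = np.asarray(points, float)
    scope = np.nonzero(labels != None)[0]  # noqa: E711
    if len(scope) == 0:
        return labels, {}, 0
    pts = points[scope]
    tree = cKDTree(pts)
    kq = min(k + 1, len(scope))
    _, nbrs = tree.query(pts, k=kq)
    nbrs = np.atleast_2d(nbrs)
    if nbrs.shape[0] != len(scope):
        nbrs = nbrs.T
    it = 0
    for it in range(1, max_iter + 1):
        changed = False
        cur = labels[scope]
        # (a) rolony <- mode of k nearest neighbours (self excluded)
        new = cur.copy()
        for i in range(len(scope)):
            votes = [cur[j] for j in nbrs[i] if j != i][:k]
            lab = _mode_with_tiebreak(votes, cur[i])
            if lab != new[i]:
                new[i] = lab
        # (b) cell <- mode of its rolonies; rolonies inherit
        cell_labels: dict = {}
        for cid in np.unique(cell_ids[scope]):
            sel = cell_ids[scope] == cid
            cell_labels[cid] = _mode_with_tiebreak(list(new[sel]), None)
        for i, gi in enumerate(scope):
            lab = cell_labels[cell_ids[gi]]
            if lab != cur[i]:
                changed = True
            new[i] = lab
        labels[scope] = new
        if not changed:
            break
    else:
        logger.info("iterate_knn reached the %d-iteration cap", max_iter)
    cell_labels = {}
    for cid in np.unique(cell_ids[scope]):
        sel = cell_ids[scope] == cid
        cell_labels[cid] = _mode_with_tiebreak(list(labels[scope][sel]), None)
    return labels, cell_labels, it


def finalize_etct(
    thal_points: np.ndarray,
    thal_cell_ids: np.ndarray,
    step1_cell_labels: dict,
    k: int = 10,
) -> dict:
    """Final ET/CT call from thalamic rolonies.

    Thalamic rolonies of step-1-labeled cells form the labeled pool; every
    thalamic rolony then takes the most frequent label of its ``k``
    nearest pool rolonies, and each cell the most frequent label of its
    thalamic rolonies.  Cells without thalamic rolonies are 'unassigned'.
    """
    thal_points = np.asarray(thal_points, float)
    pool = np.array([step1_cell_labels.get(c) is not None for c in thal_cell_ids])
    out: dict = {}
    if not pool.any():
        return {c: "unassigned" for c in np.unique(thal_cell_ids)}
    pool_pts = thal_points[pool]
    pool_lab = np.array([step1_cell_labels[c] for c in thal_cell_ids[pool]], dtype=object)
    tree = cKDTree(pool_pts)
    kq = min(k, len(pool_pts))
    _, nbrs = tree.query(thal_points, k=kq)
    nbrs = np.atleast_2d(nbrs)
    if nbrs.shape[0] != len(thal_points):
        nbrs = nbrs.T
    rol_lab = np.array(
        [_mode_with_tiebreak(list(pool_lab[nbrs[i]]), None) for i in range(len(thal_points))],
        dtype=object,
    )
    for cid in np.unique(thal_cell_ids):
        sel = thal_cell_ids == cid
        out[cid] = _mode_with_tiebreak(list(rol_lab[sel]), None)
    return out


def classify_etct(
    cells: list[CellRecord],
    roi: FiberROI | None = None,
    k: int = 10,
    max_iter: int = 100,
    thalamus_regions: tuple[str, ...] = ("Thal",),
) -> tuple[dict, dict, int]:
    """Two-step ET/CT classification over a cell list.

    Step 1: seed + iterative kNN on the fiber-ROI rolonies; step 2: one
    propagation pass over thalamic rolonies.  Returns (step-1 cell labels,
    final cell labels incl. 'unassigned', iterations used).
    """
    if roi is None:
        roi = FiberROI()
    pts, cids = [], []
    for ci, cell in enumerate(cells):
        xyz = cell.rolonies[["x", "y", "z"]].to_numpy()
        pts.append(xyz)
        cids.append(np.full(len(xyz), ci))
    points = np.vstack(pts) if pts else np.zeros((0, 3))
    cell_ids = np.concatenate(cids) if cids else np.zeros(0, int)
    seeds = seed_etct(points, roi)
    _, step1, n_iter = iterate_knn(seeds, points, cell_ids, k=k, max_iter=max_iter)

    regions = np.concatenate([c.rolonies["region"].to_numpy() for c in cells]) \
        if cells else np.zeros(0, dtype=object)
    thal = np.isin(regions, thalamus_regions)
    final = finalize_etct(points[thal], cell_ids[thal], step1, k=k)
    final = {int(c): lab for c, lab in final.items()}
    return step1, final, n_iter
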