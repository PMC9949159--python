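"""Barcode and rolony quality filters.

The filter chain removes, in order: error-prone barcodes (homopolymer runs,
channel-pair bias, mismatch-dominated support), cells failing rolony-count
gates, secondary-infection contaminants (Hamming ball of radius 4 around
known contaminant barcodes), duplicate rolonies in overlapping imaging
fields, floating rolonies around the soma (or around an automatically
detected floating section for cells without a soma), and non-neural cells
lacking long-range projections.  Every stage reports in/kept/removed counts
so the chain telescopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from axonmap import codebook as cb_mod
from axonmap.codebook import Codebook, HammingConvention

#: channel pairing of the four nucleotides: Ch1/2 = G,T; Ch3/4 = A,C
CH12 = frozenset("GT")
CH34 = frozenset("AC")

#: post-registration minimum rolony counts per major target
DEFAULT_REGION_MINIMUMS = {
    "AudI": 5, "VisI": 5, "AudC": 5, "VisC": 5,  # ipsi/contra cortex
    "Thal": 5,
    "Str": 3, "SupCol": 3,  # striatum, midbrain
    "Fiber": 0,
}

#: regions scanned for floating rolonies (injection area, thalamus, visual)
FLOAT_SCAN_REGIONS = frozenset({"AudI", "Thal", "VisI", "VisC"})


@dataclass
class CellRecord:
    """One barcoded neuron as carried through the QC chain."""

    barcode: str
    rolonies: pd.DataFrame  # columns: x, y, z, section, region [, field]
    soma: tuple[float, float, float, int] | None = None  # x, y, z, section
    soma_depth: float | None = None  # % of cortical depth
    soma_counts: int = 0  # somal barcode pixel count
    flags: set = dc_field(default_factory=set)
    cell_type: str | None = None

    @property
    def region_counts(self) -> dict[str, int]:
        return self.rolonies["region"].value_counts().to_dict()

    @property
    def n_rolonies(self) -> int:
        return len(self.rolonies)


@dataclass
class QCStage:
    stage: str
    n_in: int
    n_kept: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_kept


class QCLedger(list):
    """Per-stage bookkeeping; counts telescope by construction."""

    def record(self, stage: str, n_in: int, n_kept: int) -> None:
        self.append(QCStage(stage, n_in, n_kept))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage, s.n_in, s.n_kept, s.n_removed) for s in self],
            columns=["stage", "in", "kept", "removed"],
        )


# ---------------------------------------------------------------------------
# error-prone barcode filters (codebook level)

def _max_homopolymer(barcode: str) -> int:
    best = run = 0
    prev = None
    for c in barcode:
        if c == "N":
            run, prev = 0, None
            continue
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


def filter_error_prone(
    cb: Codebook,
    mismatch_counts: pd.DataFrame | None = None,
    max_homopolymer: int = 6,
    max_channel_pair: int = 14,
    ledger: QCLedger | None = None,
) -> tuple[Codebook, pd.DataFrame]:
    """Remove barcodes prone to base-calling artifacts.

    Rules, applied in order: (1) a run of more than ``max_homopolymer``
    identical nucleotides; (2) more than ``max_channel_pair`` calls in
    channels 1/2 (G, T) or channels 3/4 (A, C); (3) more supporting
    rolonies with 1–2 mismatches than with none (``mismatch_counts``
    columns: barcode, n0, n12).  Returns the filtered codebook and a
    removal report.
    """
    entries = cb.entries.copy()
    removed = []

    def drop(mask: pd.Series, rule: str) -> None:
        nonlocal entries
        for b in entries.loc[mask, "barcode"]:
            removed.append((b, rule))
        n_in = len(entries)
        entries = entries.loc[~mask].reset_index(drop=True)
        if ledger is not None:
            ledger.record(f"error_prone:{rule}", n_in, len(entries))

    drop(entries["barcode"].map(_max_homopolymer) > max_homopolymer, "homopolymer")
    ch12 = entries["barcode"].map(lambda b: sum(c in CH12 for c in b))
    ch34 = entries["barcode"].map(lambda b: sum(c in CH34 for c in b))
    drop((ch12 > max_channel_pair) | (ch34 > max_channel_pair), "channel_pair")
    if mismatch_counts is not None and len(mismatch_counts):
        mc = mismatch_counts.set_index("barcode")
        n0 = entries["barcode"].map(mc["n0"]).fillna(0)
        n12 = entries["barcode"].map(mc["n12"]).fillna(0)
        drop(n12 > n0, "mismatch_dominated")
    report = pd.DataFrame(removed, columns=["barcode", "rule"])
    out = Codebook(entries=entries, fixed_positions=cb.fixed_positions,
                   variable_length=cb.variable_length)
    return out, report


# ---------------------------------------------------------------------------
# per-cell count gates

def apply_count_gates(
    cells: Sequence[CellRecord],
    region_minimums: dict[str, int] | None = None,
    min_region_count: int = 10,
    axonal_range: tuple[int, int] = (3, 1000),
    max_soma_counts: int = 7000,
    ledger: QCLedger | None = None,
) -> list[CellRecord]:
    """Keep cells passing all three count gates.

    Per-region counts below the post-registration minimums are zeroed
    first (sub-threshold counts are treated as noise); a cell is then kept
    iff (1) some region retains >= ``min_region_count`` rolonies, (2) the
    axonal total is within ``axonal_range``, (3) somal barcode counts are
    <= ``max_soma_counts``.
    """
    if region_minimums is None:
        region_minimums = DEFAULT_REGION_MINIMUMS
    kept = []
    for cell in cells:
        counts = dict(cell.region_counts)
        for region in counts:
            if region not in region_minimums:
                raise KeyError(f"unknown region label {region!r}")
        gated = {r: (c if c >= region_minimums[r] else 0) for r, c in counts.items()}
        axonal_total = sum(gated.values())
        ok = (
            (max(gated.values(), default=0) >= min_region_count)
            and (axonal_range[0] <= axonal_total <= axonal_range[1])
            and (cell.soma_counts <= max_soma_counts)
        )
        if ok:
            keep_regions = {r for r, c in gated.items() if c > 0}
            cell.rolonies = cell.rolonies[cell.rolonies["region"].isin(keep_regions)].reset_index(drop=True)
            kept.append(cell)
    if ledger is not None:
        ledger.record("count_gates", len(cells), len(kept))
    return kept


def exclude_secondary(
    cells: Sequence[CellRecord],
    contaminant_barcodes: Sequence[str],
    max_distance: int = 4,
    conv: HammingConvention | None = None,
    ledger: QCLedger | None = None,
) -> list[CellRecord]:
    """Drop cells within a Hamming ball of radius ``max_distance`` around
    any known contaminant barcode (permissive convention)."""
    if not contaminant_barcodes:
        if ledger is not None:
            ledger.record("secondary", len(cells), len(cells))
        return list(cells)
    if conv is None:
        conv = cb_mod.DEFAULT_CONVENTION
    C = cb_mod.encode(list(contaminant_barcodes))
    B = cb_mod.encode([c.barcode for c in cells])
    D = cb_mod.distance_matrix(B, C, conv)
    kept = [c for c, dmin in zip(cells, D.min(axis=1)) if dmin > max_distance]
    if ledger is not None:
        ledger.record("secondary", len(cells), len(kept))
    return kept


def dedup_overlap(
    rolonies: pd.DataFrame,
    radius: float = 25.0,
) -> pd.DataFrame:
    """Keep one copy of same-barcode rolonies duplicated across imaging
    fields.

    Rolonies of one barcode from *different* fields within ``radius`` μm
    are merged (connected components over cross-field proximity edges; the
    lowest-index rolony represents each component).  Same-field pairs are
    never merged — they are genuine distinct rolonies.
    Requires columns barcode, field, x, y, z.
    """
    keep_mask = np.ones(len(rolonies), dtype=bool)
    for _, grp in rolonies.groupby("barcode"):
        if grp["field"].nunique() < 2:
            continue
        pts = grp[["x", "y", "z"]].to_numpy()
        fields = grp["field"].to_numpy()
        idx = grp.index.to_numpy()
        tree = cKDTree(pts)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        if len(pairs) == 0:
            continue
        cross = pairs[fields[pairs[:, 0]] != fields[pairs[:, 1]]]
        parent = np.arange(len(grp))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in cross:
            parent[find(a)] = find(b)
        comps: dict[int, list[int]] = {}
        for i in range(len(grp)):
            comps.setdefault(find(i), []).append(i)
        for members in comps.values():
            if len(members) > 1:
                for m in sorted(members)[1:]:
                    keep_mask[rolonies.index.get_loc(idx[m])] = False
    return rolonies.loc[keep_mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# soma identification

def identify_soma(
    soma_pixels: pd.DataFrame,
    min_counts: int = 80,
    radius: float = 100.0,
) -> tuple[float, float, int] | None:
    """Locate the soma of one barcode from its soma-pixel table.

    The soma section is the one with the highest summed soma-pixel
    intensity; the location is the brightest pixel there.  The soma is
    valid only with at least ``min_counts`` same-barcode pixels within
    ``radius`` μm of that location on the soma section.  Columns:
    section, x, y, intensity (x, y in μm).
    """
    if soma_pixels is None or len(soma_pixels) == 0:
        return None
    sums = soma_pixels.groupby("section")["intensity"].sum()
    section = int(sums.idxmax())
    sec = soma_pixels[soma_pixels["section"] == section]
    brightest = sec.loc[sec["intensity"].idxmax()]
    x0, y0 = float(brightest["x"]), float(brightest["y"])
    d = np.hypot(sec["x"] - x0, sec["y"] - y0)
    if int((d <= radius).sum()) < min_counts:
        return None
    return (x0, y0, section)


# ---------------------------------------------------------------------------
# floating rolonies

def _single_linkage_clusters(pts: np.ndarray, cut: float) -> int:
    if len(pts) <= 1:
        return len(pts)
    Z = linkage(pts, method="single")
    return int(fcluster(Z, t=cut, criterion="distance").max())


def detect_floating_sections(
    rolonies: pd.DataFrame,
    scan_regions: Iterable[str] = FLOAT_SCAN_REGIONS,
    neighbor_radius: float = 140.0,
    section_gap: int = 1,
    cluster_cut: float = 50.0,
    min_clusters: int = 3,
) -> int | None:
    """Find the section carrying floating rolonies for one cell, if any.

    A rolony is a floater candidate when no same-cell rolony within
    ``neighbor_radius`` μm (tangentially) exists on a section more than
    ``section_gap`` away — floaters are section-local, axons are not.  A
    section qualifies when its candidates form >= ``min_clusters``
    single-linkage clusters at a ``cluster_cut`` μm cut (widely and
    sparsely scattered).  Among qualifying sections the one with the
    widest tangential coverage (bounding-box diagonal) is returned.
    """
    scan = rolonies[rolonies["region"].isin(set(scan_regions))]
    if len(scan) == 0:
        return None
    pts = scan[["x", "y"]].to_numpy()
    secs = scan["section"].to_numpy()
    areas = scan["region"].to_numpy()
    tree = cKDTree(pts)
    candidate = np.zeros(len(scan), dtype=bool)
    for i in range(len(scan)):
        nbrs = tree.query_ball_point(pts[i], neighbor_radius)
        far = [j for j in nbrs if abs(int(secs[j]) - int(secs[i])) > section_gap]
        candidate[i] = len(far) == 0
    # evaluate section + area pairs: "the only slide with rolonies in
    # specific areas" — coverage is meaningless across areas/hemispheres
    best_section, best_span = None, -1.0
    for s in np.unique(secs):
        for a in np.unique(areas[secs == s]):
            sel = candidate & (secs == s) & (areas == a)
            cpts = pts[sel]
            if len(cpts) < min_clusters:
                continue
            if _single_linkage_clusters(cpts, cluster_cut) < min_clusters:
                continue
            span = float(np.hypot(*(cpts.max(axis=0) - cpts.min(axis=0))))
            if span > best_span:
                best_section, best_span = int(s), span
    return best_section


def exclude_floating(
    cell: CellRecord,
    anchor_section: int | None,
    window: int = 2,
    regions: Iterable[str] = FLOAT_SCAN_REGIONS,
) -> CellRecord:
    """Drop rolonies in the scanned regions within ``window`` sections of
    the anchor (soma section, or the detected floating section).  With no
    anchor the cell passes unchanged."""
    if anchor_section is None:
        return cell
    rol = cell.rolonies
    near = (rol["section"] - anchor_section).abs() <= window
    drop = near & rol["region"].isin(set(regions))
    cell.rolonies = rol.loc[~drop].reset_index(drop=True)
    return cell


def exclude_non_neural(
    cells: Sequence[CellRecord],
    min_far_rolonies: int = 3,
    min_distance: float = 200.0,
    ledger: QCLedger | None = None,
) -> list[CellRecord]:
    """Keep cells with >= ``min_far_rolonies`` rolonies at least
    ``min_distance`` μm from the soma (or the rolony centroid when no soma
    is known) — non-neural cells lack long-range projections."""
    kept = []
    for cell in cells:
        pts = cell.rolonies[["x", "y", "z"]].to_numpy()
        if len(pts) == 0:
            continue
        anchor = np.asarray(cell.soma[:3]) if cell.soma is not None else pts.mean(axis=0)
        d = np.linalg.norm(pts - anchor, axis=1)
        if int((d >= min_distance).sum()) >= min_far_rolonies:
            kept.append(cell)
    if ledger is not None:
        ledger.record("non_neural", len(cells), len(kept))
    return kept
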