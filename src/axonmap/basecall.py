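"""Chain detected dots across sequencing cycles into rolony barcode reads.

Dots from later cycles are one-to-one matched to the closest available dot
in a previous cycle within a 5-pixel gate.  To tolerate per-cycle signal
loss, every cycle is additionally matched against the two cycles before the
previous one (cycle intervals 1, 2 and 3).  Matches are merged in ascending
interval order at each cycle boundary; a skipped cycle inside a bridged
interval is recorded as N (non-base-called).  When a new match disagrees
with an existing read, the read's prefix is duplicated (forked) so both
alternatives survive until codebook matching condenses them.  Reads with a
run of more than 3 consecutive N are discarded.

Somata are base-called per pixel rather than per local maximum, with a
phasing correction that subtracts the previous cycle's intensity (50% for
the previously dominant channel, 100% for the others).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from axonmap.simulate import ALPHABET

_LETTER = {i + 1: c for i, c in enumerate(ALPHABET)}


def _n_run(barcode: str) -> int:
    run = best = 0
    for c in barcode:
        run = run + 1 if c == "N" else 0
        best = max(best, run)
    return best


@dataclass(frozen=True)
class RolonyRead:
    """A chained dot sequence with its assembled barcode string."""

    read_id: int
    barcode: str  # length n_cycles over {G,T,A,C,N}
    dot_ids: Mapping[int, int]  # cycle (1-based) -> dot id
    x: float
    y: float
    tile: int

    @property
    def n_called(self) -> int:
        return len(self.barcode) - self.barcode.count("N")

    @property
    def max_N_run(self) -> int:
        return _n_run(self.barcode)

    def blank_cycle(self, cycle: int) -> "RolonyRead":
        bc = list(self.barcode)
        bc[cycle - 1] = "N"
        dots = {c: d for c, d in self.dot_ids.items() if c != cycle}
        return replace(self, barcode="".join(bc), dot_ids=dots)


def chain_dots(
    dots: pd.DataFrame,
    gate: float = 5.0,
    lookback: int = 3,
) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """One-to-one match dots between cycle pairs within the distance gate.

    For every ordered cycle pair ``(t - d, t)`` with ``1 <= d <= lookback``,
    candidate pairs closer than ``gate`` pixels are assigned greedily by
    ascending distance (ties broken by dot ids), so each dot participates at
    most once per cycle pair.  Chaining is performed independently per tile
    (dots on different sections cannot belong to one rolony).
    """
    matches: dict[tuple[int, int], list[tuple[int, int]]] = {}
    tiles = dots["tile"].unique() if "tile" in dots else [0]
    for tile in tiles:
        sub = dots[dots["tile"] == tile] if "tile" in dots else dots
        by_cycle = {
            int(c): g[["dot_id", "x", "y"]].to_numpy()
            for c, g in sub.groupby("cycle")
        }
        cycles = sorted(by_cycle)
        for t in cycles:
            for d in range(1, lookback + 1):
                p = t - d
                if p not in by_cycle:
                    continue
                prev, cur = by_cycle[p], by_cycle[t]
                tree = cKDTree(prev[:, 1:3])
                dist, idx = tree.query(cur[:, 1:3], k=min(8, len(prev)),
                                       distance_upper_bound=gate)
                dist = np.atleast_2d(dist.T).T
                idx = np.atleast_2d(idx.T).T
                cand = []
                for j in range(len(cur)):
                    for kk in range(dist.shape[1]):
                        if np.isfinite(dist[j, kk]) and dist[j, kk] < gate:
                            cand.append((dist[j, kk], int(prev[idx[j, kk], 0]),
                                         int(cur[j, 0])))
                cand.sort()
                used_p: set[int] = set()
                used_c: set[int] = set()
                pairs = []
                for _, pid, cid in cand:
                    if pid in used_p or cid in used_c:
                        continue
                    used_p.add(pid)
                    used_c.add(cid)
                    pairs.append((pid, cid))
                if pairs:
                    matches.setdefault((p, t), []).extend(pairs)
    return matches


def assemble_sequences(
    dots: pd.DataFrame,
    matches: Mapping[tuple[int, int], Sequence[tuple[int, int]]],
    n_cycles: int,
    lookback: int = 3,
    max_n_run: int = 3,
    max_forks: int = 4,
    reference_cycle: int | None = None,
) -> list[RolonyRead]:
    """Merge cycle-pair matches into barcode reads.

    At each cycle boundary ``t`` the intervals are applied in ascending
    order (``t-1 -> t`` before ``t-2 -> t`` before ``t-3 -> t``).  A match
    extending a read whose slot at ``t`` is already occupied by a different
    dot forks the read (full-prefix duplication); lineages exceeding
    ``max_forks`` forks are dropped.  Reads whose final string has an N-run
    longer than ``max_n_run`` are discarded.  The read position is the dot
    coordinate at the reference cycle (default: middle cycle) when present,
    else the chain centroid.
    """
    if reference_cycle is None:
        reference_cycle = (n_cycles + 1) // 2
    info = dots.set_index("dot_id")
    dot_channel = info["channel"].to_dict()
    dot_x = info["x"].to_dict()
    dot_y = info["y"].to_dict()
    dot_tile = info["tile"].to_dict() if "tile" in dots else {}

    # reads as mutable dicts cycle -> dot_id, plus lineage bookkeeping
    reads: list[dict[int, int] | None] = []
    roots: list[int] = []
    fork_count: dict[int, int] = {}
    dead_roots: set[int] = set()
    # (cycle, dot) -> read indices holding that dot at that cycle
    holder: dict[tuple[int, int], list[int]] = {}

    def new_read(content: dict[int, int]) -> int:
        idx = len(reads)
        reads.append(content)
        roots.append(idx)
        fork_count[idx] = 0
        for cyc, did in content.items():
            holder.setdefault((cyc, did), []).append(idx)
        return idx

    by_cycle_dots = {int(c): g["dot_id"].tolist() for c, g in dots.groupby("cycle")}
    for did in by_cycle_dots.get(1, []):
        new_read({1: did})

    for t in range(2, n_cycles + 1):
        for d in range(1, lookback + 1):
            p = t - d
            pairs = matches.get((p, t), [])
            for pid, cid in sorted(pairs):
                holders = list(holder.get((p, pid), []))
                if not holders:
                    new_read({p: pid, t: cid})
                    continue
                for ri in holders:
                    read = reads[ri]
                    if read is None:
                        continue
                    have = read.get(t)
                    if have is None:
                        read[t] = cid
                        holder.setdefault((t, cid), []).append(ri)
                    elif have != cid:
                        root = roots[ri]
                        fork_count[root] += 1
                        if fork_count[root] > max_forks:
                            dead_roots.add(root)
                            continue
                        forked = {c: dd for c, dd in read.items() if c != t}
                        forked[t] = cid
                        idx = len(reads)
                        reads.append(forked)
                        roots.append(root)
                        for cyc, dd in forked.items():
                            holder.setdefault((cyc, dd), []).append(idx)
        for did in by_cycle_dots.get(t, []):
            if (t, did) not in holder:
                new_read({t: did})

    out: list[RolonyRead] = []
    for ri, read in enumerate(reads):
        if read is None or roots[ri] in dead_roots:
            continue
        bc = ["N"] * n_cycles
        for cyc, did in read.items():
            bc[cyc - 1] = _LETTER[int(dot_channel[did])]
        barcode = "".join(bc)
        if _n_run(barcode) > max_n_run:
            continue
        if reference_cycle in read:
            rx, ry = dot_x[read[reference_cycle]], dot_y[read[reference_cycle]]
        else:
            xs = [dot_x[d] for d in read.values()]
            ys = [dot_y[d] for d in read.values()]
            rx, ry = float(np.mean(xs)), float(np.mean(ys))
        tile = int(dot_tile.get(next(iter(read.values())), 0)) if dot_tile else 0
        out.append(RolonyRead(
            read_id=len(out), barcode=barcode, dot_ids=dict(read),
            x=float(rx), y=float(ry), tile=tile,
        ))
    return out


def exclude_perisomatic(
    reads: Sequence[RolonyRead],
    soma_pixels: pd.DataFrame | None,
    radius_um: float = 20.0,
    pixel_size: float = 0.55,
    min_pixels: int = 35,
    min_cycles: int = 2,
) -> list[RolonyRead]:
    """Drop reads in the dense perisomatic zone.

    A read is removed iff in *more than* ``min_cycles`` cycles at least
    ``min_pixels`` soma pixels (same tile) lie within ``radius_um`` of it.
    ``soma_pixels`` needs columns tile, cycle, x, y (pixel units); with no
    soma map the reads pass through unchanged.
    """
    if soma_pixels is None or len(soma_pixels) == 0:
        return list(reads)
    radius_px = radius_um / pixel_size
    trees = {
        (int(t), int(c)): cKDTree(g[["x", "y"]].to_numpy())
        for (t, c), g in soma_pixels.groupby(["tile", "cycle"])
    }
    cycles = sorted(soma_pixels["cycle"].unique())
    kept = []
    for r in reads:
        n_dense = 0
        for c in cycles:
            tree = trees.get((r.tile, int(c)))
            if tree is None:
                continue
            if len(tree.query_ball_point([r.x, r.y], radius_px)) >= min_pixels:
                n_dense += 1
                if n_dense > min_cycles:
                    break
        if n_dense <= min_cycles:
            kept.append(r)
    return kept


@dataclass
class SomaBarcodeMap:
    """Per-pixel soma base-calls: ``calls[t, y, x]`` in 0..4 (0 = N)."""

    calls: np.ndarray  # (n_cycles, H, W) int8
    corrected: np.ndarray  # (n_cycles, 4, H, W) float

    def barcode_at(self, y: int, x: int) -> str:
        return "".join("N" if v == 0 else _LETTER[int(v)] for v in self.calls[:, y, x])


def basecall_soma(
    intensities: np.ndarray,
    phasing_max: float = 0.5,
    phasing_rest: float = 1.0,
) -> SomaBarcodeMap:
    """Base-call soma pixels with phasing correction.

    ``intensities`` has shape (n_cycles, 4, H, W).  For every cycle after
    the first, the previous cycle's intensity is subtracted channel-wise:
    50% for the channel that was the previous argmax, 100% for the rest;
    negatives clip to zero.  The call is the argmax of the corrected
    channels; an all-zero pixel is N.
    """
    I = np.asarray(intensities, dtype=float)
    n_cycles, n_ch, H, W = I.shape
    corrected = np.empty_like(I)
    corrected[0] = I[0]
    for t in range(1, n_cycles):
        prev = I[t - 1]
        prev_arg = np.argmax(prev, axis=0)  # (H, W)
        factor = np.full((n_ch, H, W), phasing_rest)
        np.put_along_axis(factor, prev_arg[None], phasing_max, axis=0)
        corrected[t] = np.clip(I[t] - factor * prev, 0, None)
    calls = (np.argmax(corrected, axis=1) + 1).astype(np.int8)
    calls[corrected.max(axis=1) <= 0] = 0
    return SomaBarcodeMap(calls=calls, corrected=corrected)


def reads_to_frame(reads: Sequence[RolonyRead]) -> pd.DataFrame:
    """Tabulate reads (barcode, x, y, tile, n_called, max_N_run)."""
    return pd.DataFrame({
        "read_id": [r.read_id for r in reads],
        "barcode": [r.barcode for r in reads],
        "x": [r.x for r in reads],
        "y": [r.y for r in reads],
        "tile": [r.tile for r in reads],
        "n_called": [r.n_called for r in reads],
        "max_N_run": [r.max_N_run for r in reads],
    })
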