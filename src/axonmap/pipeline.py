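"""End-to-end wiring of the dot-table pipeline, plus ground-truth audits.

The canonical processing path on pre-detected (or simulated) dot tables:

1. chain dots across cycles and assemble barcode reads
   (:mod:`axonmap.basecall`),
2. build the codebook from the read barcodes and match every read back to
   it (:mod:`axonmap.codebook`),
3. condense multiply-called rolonies,
4. aggregate matched reads into per-barcode cell records with μm
   positions and region labels (ready for :mod:`axonmap.qc`).

The audit helpers compare pipeline output against the simulation's
ground-truth linkage; the pipeline itself never reads the linkage columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from axonmap import basecall, codebook as cb_mod
from axonmap.codebook import Codebook
from axonmap.qc import CellRecord
from axonmap.simulate import SimConfig

#: region lookup order — the fiber box is nested between larger targets
REGION_ORDER = ("Fiber", "AudI", "VisI", "AudC", "VisC", "Thal", "Str", "SupCol")


def assign_regions(points_um: np.ndarray, regions: Mapping[str, tuple]) -> np.ndarray:
    """Label μm points by the first containing region box (else '')."""
    pts = np.asarray(points_um, float)
    out = np.full(len(pts), "", dtype=object)
    order = [r for r in REGION_ORDER if r in regions]
    order += [r for r in regions if r not in order]
    for name in order:
        box = regions[name]
        inside = np.ones(len(pts), dtype=bool)
        for ax in range(3):
            inside &= (pts[:, ax] >= box[ax][0]) & (pts[:, ax] <= box[ax][1])
        out[inside & (out == "")] = name
    return out


@dataclass
class PipelineResult:
    reads: list[basecall.RolonyRead]
    codebook: Codebook
    matches: pd.DataFrame  # aligned with reads
    condensed_reads: list[basecall.RolonyRead]
    condensed_matches: pd.DataFrame
    cells: dict[str, CellRecord]


def run(
    dots: pd.DataFrame,
    cfg: SimConfig,
    gate: float = 5.0,
    lookback: int = 3,
    max_match_distance: int = 2,
) -> PipelineResult:
    """Run base-calling, codebook construction and matching on a dot table.

    ``dots`` must carry dot_id, cycle, tile, x, y (pixels), channel; extra
    columns are ignored.  Cycles are assumed registered into a common
    per-tile frame (apply :mod:`axonmap.register` first otherwise).
    """
    matches_by_pair = basecall.chain_dots(dots, gate=gate, lookback=lookback)
    reads = basecall.assemble_sequences(dots, matches_by_pair, cfg.n_cycles,
                                        lookback=lookback)
    cb = cb_mod.build_codebook(
        [r.barcode for r in reads], fixed_positions=cfg.fixed_positions,
    )
    matches = cb_mod.match_to_codebook([r.barcode for r in reads], cb,
                                       max_distance=max_match_distance)
    condensed, cond_matches = cb_mod.condense_reads(reads, matches)
    cells = build_cells(condensed, cond_matches, cfg)
    return PipelineResult(reads=reads, codebook=cb, matches=matches,
                          condensed_reads=condensed,
                          condensed_matches=cond_matches, cells=cells)


def build_cells(
    reads: Sequence[basecall.RolonyRead],
    matches: pd.DataFrame,
    cfg: SimConfig,
) -> dict[str, CellRecord]:
    """Aggregate matched reads into per-barcode cell records (μm frame)."""
    bc_of_read = dict(zip(matches["read_id"], matches["barcode"]))
    rows: dict[str, list] = {}
    for r in reads:
        bc = bc_of_read.get(r.read_id)
        if bc is None:
            continue
        x = r.x * cfg.pixel_size
        y = r.y * cfg.pixel_size
        z = cfg.z_origin + (r.tile + 0.5) * cfg.section_thickness
        rows.setdefault(bc, []).append((x, y, z, r.tile, r.read_id))
    cells = {}
    for bc, rr in rows.items():
        df = pd.DataFrame(rr, columns=["x", "y", "z", "section", "read_id"])
        df["region"] = assign_regions(df[["x", "y", "z"]].to_numpy(), cfg.regions)
        df["field"] = df["section"]
        cells[bc] = CellRecord(barcode=bc, rolonies=df)
    return cells


# ---------------------------------------------------------------------------
# ground-truth audits (simulation only)

def true_barcode_of_reads(
    reads: Sequence[basecall.RolonyRead],
    dots: pd.DataFrame,
    truth: pd.DataFrame,
) -> list[str | None]:
    """Dominant ground-truth barcode per read (mode over its dots)."""
    dot_to_rol = dict(zip(dots["dot_id"], dots["rolony_id"]))
    rol_to_bc = dict(zip(truth["rolony_id"], truth["barcode"]))
    out = []
    for r in reads:
        bcs = [rol_to_bc[dot_to_rol[d]] for d in r.dot_ids.values()]
        out.append(max(set(bcs), key=bcs.count) if bcs else None)
    return out


def _compatible(entries: Sequence[str], truths: Sequence[str]) -> np.ndarray:
    """Boolean (n_entries, n_truths): zero permissive mismatches at all
    positions — an entry with residual N still identifies its barcode."""
    if len(entries) == 0 or len(truths) == 0:
        return np.zeros((len(entries), len(truths)), dtype=bool)
    conv = cb_mod.HammingConvention(mode="permissive_N", exclude_positions=frozenset())
    D = cb_mod.distance_matrix(cb_mod.encode(list(entries)),
                               cb_mod.encode(list(truths)), conv)
    return D == 0


def codebook_recall_precision(
    cb: Codebook, neuron_barcodes: Sequence[str],
    contaminant_barcodes: Sequence[str] = (),
) -> tuple[float, float]:
    """Recall over neuron barcodes; precision over all true barcodes
    (neurons plus contaminants — secondary-infection barcodes are real).

    Codebook entries may carry up to two uncalled positions; an entry
    counts as recovering a barcode when it is permissively compatible
    with it and with no other true barcode.
    """
    truth = list(dict.fromkeys(neuron_barcodes))
    all_true = truth + [b for b in dict.fromkeys(contaminant_barcodes) if b not in truth]
    comp = _compatible(cb.barcodes, all_true)
    unambiguous = comp & (comp.sum(axis=1, keepdims=True) == 1)
    n_truth = len(truth)
    recall = float(unambiguous[:, :n_truth].any(axis=0).mean()) if n_truth else float("nan")
    precision = float(comp.any(axis=1).mean()) if len(cb) else float("nan")
    return recall, precision


def misassignment_rate(
    reads: Sequence[basecall.RolonyRead],
    matches: pd.DataFrame,
    dots: pd.DataFrame,
    truth: pd.DataFrame,
) -> float:
    """Fraction of matched reads assigned to a codebook entry that is not
    permissively compatible with their dominant ground-truth barcode."""
    true_bc = true_barcode_of_reads(reads, dots, truth)
    n_matched = n_wrong = 0
    for i in range(len(reads)):
        if matches["verdict"].iat[i] != "matched":
            continue
        n_matched += 1
        entry = matches["barcode"].iat[i]
        if entry != true_bc[i] and not _compatible([entry], [true_bc[i]])[0, 0]:
            n_wrong += 1
    return n_wrong / n_matched if n_matched else float("nan")
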