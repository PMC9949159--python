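"""Barcode/rolony filter chain: each rule's thresholds, idempotence, and
the telescoping stage ledger."""

import numpy as np
import pandas as pd
import pytest

from axonmap.codebook import build_codebook
from axonmap.qc import (
    CellRecord,
    QCLedger,
    apply_count_gates,
    dedup_overlap,
    detect_floating_sections,
    exclude_floating,
    exclude_non_neural,
    exclude_secondary,
    filter_error_prone,
    identify_soma,
)

GOOD = "GTACGTACGGGTACGTA"


def _cell(rows, barcode=GOOD, **kw):
    df = pd.DataFrame(rows, columns=["x", "y", "z", "section", "region"])
    return CellRecord(barcode=barcode, rolonies=df, **kw)


def _cluster(region, n, center, section, spread=5.0, seed=0):
    rng = np.random.default_rng(seed)
    return [(center[0] + rng.normal(0, spread), center[1] + rng.normal(0, spread),
             center[2], section, region) for _ in range(n)]


class TestErrorProne:
    def _cb(self, barcodes):
        return build_codebook([b for b in barcodes for _ in range(3)])

    def test_homopolymer_run_removed(self):
        bad = "GGGGGGG" + "TACATAGCAT"  # 7-G run
        cb = self._cb([bad, GOOD])
        out, report = filter_error_prone(cb)
        assert bad not in out.barcodes and GOOD in out.barcodes
        assert (report["rule"] == "homopolymer").sum() == 1

    def test_channel_pair_bias_removed(self):
        biased = "GTGTGTGTGGGTGTGTA"  # 16 calls in channels 1/2 (G,T)
        cb = self._cb([biased, GOOD])
        out, report = filter_error_prone(cb)
        assert biased not in out.barcodes
        assert (report["rule"] == "channel_pair").sum() == 1

    def test_mismatch_dominated_removed(self):
        cb = self._cb([GOOD])
        mc = pd.DataFrame({"barcode": [GOOD], "n0": [5], "n12": [6]})
        out, report = filter_error_prone(cb, mismatch_counts=mc)
        assert len(out) == 0
        assert (report["rule"] == "mismatch_dominated").sum() == 1

    def test_exact_majority_kept(self):
        cb = self._cb([GOOD])
        mc = pd.DataFrame({"barcode": [GOOD], "n0": [6], "n12": [6]})
        out, _ = filter_error_prone(cb, mismatch_counts=mc)
        assert GOOD in out.barcodes

    def test_idempotent(self):
        cb = self._cb([GOOD, "GGGGGGG" + "TACATAGCAT"])
        once, _ = filter_error_prone(cb)
        twice, rep2 = filter_error_prone(once)
        assert once.barcodes == twice.barcodes and len(rep2) == 0


class TestCountGates:
    def test_passing_cell_kept(self):
        cell = _cell(_cluster("Thal", 12, (7000, 4000, 7000), 10), soma_counts=100)
        assert apply_count_gates([cell]) == [cell]

    def test_max_region_below_ten_removed(self):
        cell = _cell(_cluster("Thal", 9, (7000, 4000, 7000), 10))
        assert apply_count_gates([cell]) == []

    def test_axonal_total_above_1000_removed(self):
        cell = _cell(_cluster("Thal", 1500, (7000, 4000, 7000), 10))
        assert apply_count_gates([cell]) == []

    def test_soma_count_gate(self):
        cell = _cell(_cluster("Thal", 12, (7000, 4000, 7000), 10), soma_counts=7001)
        assert apply_count_gates([cell]) == []

    def test_subthreshold_region_zeroed(self):
        rows = _cluster("Thal", 12, (7000, 4000, 7000), 10) + \
            _cluster("Str", 2, (9000, 3000, 6500), 5)  # below the Str minimum of 3
        cell = _cell(rows)
        kept = apply_count_gates([cell])
        assert kept and "Str" not in kept[0].region_counts

    def test_unknown_region_errors(self):
        cell = _cell([(0, 0, 0, 0, "Nowhere")] * 12)
        with pytest.raises(KeyError):
            apply_count_gates([cell])


class TestSecondary:
    def test_contaminant_and_ball_removed(self):
        cells = [_cell([], barcode=GOOD)]
        assert exclude_secondary(cells, [GOOD]) == []
        near4 = "TTTT" + GOOD[4:]  # distance 4
        assert exclude_secondary([_cell([], barcode=near4)], [GOOD]) == []

    def test_distance_five_kept(self):
        far5 = "TTCGTG" + GOOD[6:]  # distance 5 from GOOD (pos 2 unchanged)
        kept = exclude_secondary([_cell([], barcode=far5)], [GOOD])
        assert len(kept) == 1

    def test_empty_contaminants_identity(self):
        cells = [_cell([], barcode=GOOD)]
        assert exclude_secondary(cells, []) == cells


class TestDedup:
    def _rol(self, rows):
        return pd.DataFrame(rows, columns=["barcode", "field", "x", "y", "z"])

    def test_cross_field_duplicate_within_25um_merged(self):
        df = self._rol([(GOOD, 0, 0.0, 0.0, 0.0), (GOOD, 1, 10.0, 0.0, 0.0)])
        assert len(dedup_overlap(df)) == 1

    def test_pair_beyond_25um_kept(self):
        df = self._rol([(GOOD, 0, 0.0, 0.0, 0.0), (GOOD, 1, 30.0, 0.0, 0.0)])
        assert len(dedup_overlap(df)) == 2

    def test_same_field_pair_kept(self):
        df = self._rol([(GOOD, 0, 0.0, 0.0, 0.0), (GOOD, 0, 10.0, 0.0, 0.0)])
        assert len(dedup_overlap(df)) == 2

    def test_idempotent(self):
        df = self._rol([(GOOD, 0, 0.0, 0.0, 0.0), (GOOD, 1, 10.0, 0.0, 0.0),
                        (GOOD, 1, 100.0, 0.0, 0.0)])
        once = dedup_overlap(df)
        assert dedup_overlap(once).equals(once)


class TestIdentifySoma:
    def _pixels(self, n, section=5, x=0.0, y=0.0, intensity=100.0):
        rng = np.random.default_rng(1)
        return pd.DataFrame({
            "section": section, "x": x + rng.uniform(-40, 40, n),
            "y": y + rng.uniform(-40, 40, n), "intensity": intensity,
        })

    def test_bright_cluster_located(self):
        px = self._pixels(120)
        loc = identify_soma(px)
        assert loc is not None and loc[2] == 5

    def test_79_counts_insufficient(self):
        assert identify_soma(self._pixels(79)) is None

    def test_no_pixels_no_soma(self):
        assert identify_soma(pd.DataFrame(columns=["section", "x", "y", "intensity"])) is None

    def test_section_with_highest_sum_intensity_wins(self):
        weak = self._pixels(100, section=3, intensity=10.0)
        strong = self._pixels(100, section=7, intensity=100.0)
        loc = identify_soma(pd.concat([weak, strong], ignore_index=True))
        assert loc[2] == 7


class TestFloating:
    def _axon_cell(self):
        rows = []
        for s in range(0, 30, 2):  # continuous axon through Thal
            rows += _cluster("Thal", 3, (7000, 4000, 6760 + 20 * s), s, seed=s)
        return rows

    def test_planted_floater_section_flagged(self):
        rng = np.random.default_rng(3)
        rows = self._axon_cell()
        # wide sparse disk on section 15 only, in AudI
        for i in range(8):
            rows.append((9000 + rng.uniform(-600, 600), 1500 + rng.uniform(-600, 600),
                         6700.0, 15, "AudI"))
        cell = _cell(rows)
        flagged = detect_floating_sections(cell.rolonies)
        assert flagged == 15

    def test_continuous_axon_not_flagged(self):
        assert detect_floating_sections(_cell(self._axon_cell()).rolonies) is None

    def test_two_candidates_insufficient(self):
        rows = [(9000.0, 1500.0, 6700.0, 15, "AudI"),
                (9500.0, 2000.0, 6700.0, 15, "AudI")]
        assert detect_floating_sections(_cell(rows).rolonies) is None

    def test_exclude_floating_window_and_regions(self):
        rows = [
            (9000.0, 1500.0, 6700.0, 15, "AudI"),   # inside window, scanned
            (9000.0, 1500.0, 6800.0, 20, "AudI"),   # 5 sections away
            (9000.0, 3000.0, 6500.0, 15, "Str"),    # anchor section, unscanned
        ]
        cell = exclude_floating(_cell(rows), anchor_section=15, window=2)
        assert len(cell.rolonies) == 2
        assert set(cell.rolonies["region"]) == {"AudI", "Str"}
        assert (cell.rolonies["section"] != 15).sum() == 1

    def test_no_anchor_identity(self):
        cell = _cell([(9000.0, 1500.0, 6700.0, 15, "AudI")])
        assert len(exclude_floating(cell, None).rolonies) == 1

    def test_exclude_floating_idempotent(self):
        rows = self._axon_cell() + [(9000.0, 1500.0, 6700.0, 15, "AudI")]
        once = exclude_floating(_cell(rows), 15)
        n_once = len(once.rolonies)
        assert len(exclude_floating(once, 15).rolonies) == n_once


class TestNonNeural:
    def test_compact_cluster_removed(self):
        rows = _cluster("AudI", 20, (9000, 1500, 6700), 10, spread=40.0)
        assert exclude_non_neural([_cell(rows)]) == []

    def test_three_far_rolonies_kept(self):
        rows = _cluster("AudI", 5, (9000, 1500, 6700), 10, spread=5.0)
        rows += [(9400.0, 1500.0, 6700.0, 10, "AudI")] * 3  # > 200 μm out
        cell = _cell(rows, soma=(9000.0, 1500.0, 6700.0, 10))
        assert exclude_non_neural([cell]) == [cell]

    def test_two_far_rolonies_removed(self):
        rows = _cluster("AudI", 5, (9000, 1500, 6700), 10, spread=5.0)
        rows += [(9400.0, 1500.0, 6700.0, 10, "AudI")] * 2
        cell = _cell(rows, soma=(9000.0, 1500.0, 6700.0, 10))
        assert exclude_non_neural([cell]) == []


def test_ledger_telescopes_through_chain():
    ledger = QCLedger()
    cells = [
        _cell(_cluster("Thal", 12, (7000, 4000, 7000), 10), barcode=GOOD),
        _cell(_cluster("Thal", 5, (7000, 4000, 7000), 10),
              barcode="CATG" + GOOD[4:]),
        _cell(_cluster("AudI", 15, (9000, 1500, 6700), 10, spread=30.0),
              barcode="TTTTT" + GOOD[5:]),
    ]
    kept = apply_count_gates(cells, ledger=ledger)
    kept = exclude_secondary(kept, ["AAAA" + GOOD[4:]], ledger=ledger)
    kept = exclude_non_neural(kept, ledger=ledger)
    df = ledger.to_frame()
    assert (df["in"] == df["kept"] + df["removed"]).all()
    for i in range(1, len(df)):
        assert df["in"].iloc[i] == df["kept"].iloc[i - 1]
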