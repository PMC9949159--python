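"""Hamming conventions, codebook construction and lookup matching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axonmap.basecall import RolonyRead
from axonmap.codebook import (
    DEFAULT_CONVENTION,
    LOOKUP_CONVENTION,
    HammingConvention,
    barcode_space_size,
    build_codebook,
    condense_reads,
    hamming,
    match_to_codebook,
    one_neighbor_probability,
)
from axonmap.simulate import SimConfig, generate_barcode_library

ALL_INCLUDED = HammingConvention(mode="permissive_N", exclude_positions=frozenset())


def _strict_oracle(a: str, b: str) -> int:
    """Independent oracle for the strict-lookup rule: enumerate every
    nucleotide substitution of each string's N positions (independently);
    the distance is 0 when some substitution pair matches perfectly, else
    the worst-case mismatch count over substitutions."""
    na = [i for i in range(len(a)) if a[i] == "N"]
    nb = [i for i in range(len(b)) if b[i] == "N"]
    dists = []
    for sub_a in itertools.product("GTAC", repeat=len(na)):
        aa = list(a)
        for i, c in zip(na, sub_a):
            aa[i] = c
        for sub_b in itertools.product("GTAC", repeat=len(nb)):
            bb = list(b)
            for i, c in zip(nb, sub_b):
                bb[i] = c
            dists.append(sum(x != y for x, y in zip(aa, bb)))
    if min(dists) == 0:
        return 0
    return max(dists)


class TestHamming:
    def test_identity_zero(self):
        b = "GTACGTACGGGTACGTA"
        assert hamming(b, b) == 0

    def test_single_n_matches_everything_strict(self):
        a = "GTACGTACGGGTACGTA"
        b = a[:3] + "N" + a[4:]
        assert hamming(a, b, LOOKUP_CONVENTION) == 0

    def test_n_plus_mismatch_counts_both_strict(self):
        a = "GTACGTACGGGTACGTA"
        b = "T" + a[1:3] + "N" + a[4:]  # one mismatch + one N
        assert hamming(a, b, LOOKUP_CONVENTION) == 2
        assert hamming(a, b, LOOKUP_CONVENTION) == _strict_oracle(a, b)

    def test_fixed_positions_excluded_by_default(self):
        a = "GTACGTACGGGTACGTA"
        b = a[:8] + "TT" + a[10:]  # change positions 9-10
        assert hamming(a, b, DEFAULT_CONVENTION) == 0
        assert hamming(a, b, ALL_INCLUDED) == 2

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            hamming("GTAC", "GTACG")

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_metric_on_n_free_strings(self, data):
        strat = st.text(alphabet="GTAC", min_size=8, max_size=8)
        a, b, c = (data.draw(strat) for _ in range(3))
        conv = HammingConvention(mode="permissive_N", exclude_positions=frozenset())
        dab = hamming(a, b, conv)
        assert dab == hamming(b, a, conv)  # symmetry
        assert dab <= hamming(a, c, conv) + hamming(c, b, conv)  # triangle
        assert (dab == 0) == (a == b)

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strict_lookup_matches_enumeration_oracle(self, data):
        def with_ns(s, positions):
            return "".join("N" if i in positions else c for i, c in enumerate(s))

        base = st.text(alphabet="GTAC", min_size=6, max_size=6)
        pos = st.sets(st.integers(0, 5), max_size=2)
        a = with_ns(data.draw(base), data.draw(pos))
        b = with_ns(data.draw(base), data.draw(pos))
        conv = HammingConvention(mode="strict_lookup", exclude_positions=frozenset())
        assert hamming(a, b, conv) == _strict_oracle(a, b)


class TestClosedForms:
    def test_barcode_space_is_exact_power(self):
        assert barcode_space_size(30) == 4**30
        assert barcode_space_size(30) >= 10**18

    def test_one_neighbor_probability_monotone_and_small(self):
        p = one_neighbor_probability(13_919)
        assert 0 < p < 0.001
        assert one_neighbor_probability(100_000) > p


def _read(bc, rid=0, dots=None, x=0.0):
    if dots is None:
        dots = {c + 1: rid * 100 + c for c in range(len(bc)) if bc[c] != "N"}
    return RolonyRead(read_id=rid, barcode=bc, dot_ids=dots, x=x, y=0.0, tile=0)


class TestBuildCodebook:
    def test_error_copy_absorbed_into_majority(self):
        x = "GTACGTACGGGTACGTA"
        err = "T" + x[1:]
        cb = build_codebook([x] * 5 + [err])
        assert cb.barcodes == [x]
        assert int(cb.entries["support"].iloc[0] + cb.entries["absorbed_support"].iloc[0]) == 6

    def test_two_copies_insufficient(self):
        y = "GTACGTACGGGTACGTA"
        assert len(build_codebook([y, y])) == 0

    def test_homogeneous_barcode_rejected(self):
        # >13 identical nucleotides violates the composition limit
        bad = "G" * 17
        assert len(build_codebook([bad] * 5)) == 0

    def test_n_reads_collapse_into_full_barcode(self):
        x = "GTACGTACGGGTACGTA"
        partial = x[:5] + "N" + x[6:]
        cb = build_codebook([x, x, partial])
        assert cb.barcodes == [x]
        assert int(cb.entries["support"].iloc[0]) == 3

    def test_simulated_library_full_recall(self):
        cfg = SimConfig(seed=21)
        rng = np.random.default_rng(5)
        lib = generate_barcode_library(100, cfg, rng)
        reads = []
        for b in lib:
            for _ in range(30):
                bc = list(b)
                for i in range(17):
                    if rng.random() < 0.01:
                        bc[i] = "GTAC"[rng.integers(4)]
                reads.append("".join(bc))
        cb = build_codebook(reads)
        assert set(cb.barcodes) == set(lib)  # recall and precision = 1

    def test_greedy_equals_brute_force_oracle(self):
        # independent re-evaluation of the acceptance rules on <= 500 reads
        cfg = SimConfig(seed=33)
        rng = np.random.default_rng(7)
        lib = generate_barcode_library(30, cfg, rng)
        reads = []
        for b in lib:
            reads += [b] * int(rng.integers(1, 8))
        cb = build_codebook(reads)

        from collections import Counter
        counts = Counter(reads)
        accepted = []
        for b, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            if c < 3:
                continue
            if max(Counter(b).values()) > 13:
                continue
            var = [ch for i, ch in enumerate(b) if i not in (8, 9)]
            if sum(ch != "N" for ch in var) < 13:
                continue
            near = False
            for a in accepted:
                d = sum(x != y for i, (x, y) in enumerate(zip(a, b)) if i not in (8, 9))
                if d <= 1:
                    near = True
            if not near:
                accepted.append(b)
        assert set(cb.barcodes) == set(accepted)

    def test_pairwise_min_distance_at_least_two(self):
        cfg = SimConfig(seed=2)
        lib = generate_barcode_library(200, cfg)
        cb = build_codebook([b for b in lib for _ in range(3)])
        bs = cb.barcodes
        for i in range(len(bs)):
            for j in range(i + 1, len(bs)):
                assert hamming(bs[i], bs[j], DEFAULT_CONVENTION) >= 2

    def test_empty_input(self):
        assert len(build_codebook([])) == 0


class TestMatchToCodebook:
    @pytest.fixture
    def cb(self):
        entries = ["GTACGTACGGGTACGTA", "CCCGTACGGGATGGTAC"]
        return build_codebook([b for b in entries for _ in range(3)])

    def test_exact_match_distance_zero(self, cb):
        m = match_to_codebook([cb.barcodes[0]], cb)
        assert m["verdict"].iloc[0] == "matched" and m["distance"].iloc[0] == 0

    def test_distance_two_unique_matched(self, cb):
        q = "TT" + cb.barcodes[0][2:]
        m = match_to_codebook([q], cb)
        assert m["verdict"].iloc[0] == "matched"
        assert m["distance"].iloc[0] == 2
        assert m["barcode"].iloc[0] == cb.barcodes[0]

    def test_distance_three_unmatched(self, cb):
        q = "TTT" + cb.barcodes[0][3:]
        assert match_to_codebook([q], cb)["verdict"].iloc[0] == "unmatched"

    def test_fixed_positions_count_at_lookup(self, cb):
        # matching includes ALL positions: 2 changes at 9-10 plus one more
        # put the query at distance 3
        b = cb.barcodes[0]
        q = b[:8] + "TT" + b[10:]
        q = "A" + q[1:] if q[0] != "A" else "G" + q[1:]
        assert match_to_codebook([q], cb)["verdict"].iloc[0] == "unmatched"

    def test_equidistant_tie_ambiguous(self):
        a = "GTACGTACGGGTACGTA"
        b = "TTACGTACGGGTACGTC"  # distance 1 from the midpoint query below
        cb = build_codebook([a] * 3 + [b] * 3)
        assert len(cb) == 2
        q = "TTACGTACGGGTACGTA"  # d=1 to a (pos 1), d=1 to b (pos 17)
        m = match_to_codebook([q], cb)
        assert m["verdict"].iloc[0] == "ambiguous"


class TestCondense:
    def test_forked_reads_with_shared_dots_collapse(self):
        bc = "GTACGTACGGGTACGTA"
        dots = {c + 1: c for c in range(17)}
        r1 = _read(bc, rid=0, dots=dots)
        d2 = dict(dots)
        d2.pop(17)
        r2 = _read(bc[:-1] + "N", rid=1, dots=d2)
        cb = build_codebook([bc] * 3)
        matches = match_to_codebook([r1.barcode, r2.barcode], cb)
        kept, km = condense_reads([r1, r2], matches)
        assert len(kept) == 1 and kept[0].read_id == 0  # most base-called wins

    def test_disjoint_reads_unchanged(self):
        bc = "GTACGTACGGGTACGTA"
        r1 = _read(bc, rid=0, dots={c + 1: c for c in range(17)})
        r2 = _read(bc, rid=1, dots={c + 1: 100 + c for c in range(17)})
        cb = build_codebook([bc] * 3)
        matches = match_to_codebook([r1.barcode, r2.barcode], cb)
        kept, _ = condense_reads([r1, r2], matches)
        assert len(kept) == 2

    def test_multiply_claimed_dot_blanked_and_read_dropped(self):
        # two different barcodes share dots in 4 cycles; blanking those
        # cycles pushes one read over the N-run limit
        a = "GTACGTACGGGTACGTA"
        b = "CATGCATGGGCATGCAT"
        cb = build_codebook([a] * 3 + [b] * 3)
        shared = {5: 900, 6: 901, 7: 902, 8: 903}
        da = {c + 1: c for c in range(17)} | shared
        db = {c + 1: 200 + c for c in range(17)} | shared
        ra = _read(a, rid=0, dots=da)
        rb = _read(b, rid=1, dots=db)
        matches = match_to_codebook([a, b], cb)
        kept, _ = condense_reads([ra, rb], matches)
        assert kept == []  # both fall to an N-run of 4
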