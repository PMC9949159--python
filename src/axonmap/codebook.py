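"""Codebook construction and Hamming-distance barcode matching.

A *codebook* is the inferred set of true barcodes present in an experiment.
It is built from axonal rolony reads under four assumptions: a true barcode
is seen in multiple rolonies (>= 3), has a higher count than its erroneous
versions, has no 1-Hamming neighbour among other true barcodes, and obeys
composition limits (< 14 identical nucleotides; >= 13 of 15 variable
positions base-called; no run of > 3 uncalled positions).

Two Hamming conventions are used at different pipeline stages:

``permissive_N``
    An uncalled position (N) matches every nucleotide; library-design fixed
    positions (default 9 and 10, 1-based) are excluded from the distance.
    Used for codebook construction and contaminant exclusion.

``strict_lookup``
    Used when matching reads against a built codebook.  All positions are
    included.  With ``m`` mismatches at doubly-called positions and ``k``
    positions where either string is N, the distance is ``m`` if ``m == 0``
    and ``m + k`` otherwise — an N is free only for otherwise-perfect
    matches.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: integer encoding of barcode characters; 0 is reserved for N (uncalled)
CHAR_CODES = {"N": 0, "G": 1, "T": 2, "A": 3, "C": 4}
CODE_CHARS = "NGTAC"


def encode(barcodes: Sequence[str]) -> np.ndarray:
    """Encode barcode strings into an (n, L) int8 array (N -> 0)."""
    if len(barcodes) == 0:
        return np.zeros((0, 0), dtype=np.int8)
    L = len(barcodes[0])
    out = np.empty((len(barcodes), L), dtype=np.int8)
    lut = np.zeros(128, dtype=np.int8)
    for ch, v in CHAR_CODES.items():
        lut[ord(ch)] = v
    for i, b in enumerate(barcodes):
        if len(b) != L:
            raise ValueError("barcodes must have equal length")
        out[i] = lut[np.frombuffer(b.encode(), dtype=np.uint8)]
    return out


@dataclass(frozen=True)
class HammingConvention:
    mode: str = "permissive_N"  # or "strict_lookup"
    exclude_positions: frozenset[int] = frozenset({9, 10})  # 1-based

    def include_mask(self, length: int) -> np.ndarray:
        mask = np.ones(length, dtype=bool)
        for p in self.exclude_positions:
            if not 1 <= p <= length:
                raise ValueError(f"excluded position {p} outside barcode")
            mask[p - 1] = False
        return mask


DEFAULT_CONVENTION = HammingConvention()
LOOKUP_CONVENTION = HammingConvention(mode="strict_lookup", exclude_positions=frozenset())


def _pair_distance(a: np.ndarray, b: np.ndarray, conv: HammingConvention) -> int:
    mask = conv.include_mask(a.shape[-1])
    both = (a > 0) & (b > 0) & mask
    m = int(np.count_nonzero(both & (a != b)))
    if conv.mode == "permissive_N":
        return m
    k = int(np.count_nonzero(((a == 0) | (b == 0)) & mask))
    return m if m == 0 else m + k


def hamming(a: str, b: str, conv: HammingConvention = DEFAULT_CONVENTION) -> int:
    """Hamming distance between two barcodes under ``conv``."""
    if len(a) != len(b):
        raise ValueError("barcodes must have equal length")
    ea, eb = encode([a, b])
    return _pair_distance(ea, eb, conv)


def distance_matrix(A: np.ndarray, B: np.ndarray, conv: HammingConvention) -> np.ndarray:
    """All-pairs distances between encoded barcode arrays (nA, nB)."""
    if A.size == 0 or B.size == 0:
        return np.zeros((A.shape[0], B.shape[0]), dtype=np.int32)
    mask = conv.include_mask(A.shape[1])
    a = A[:, None, :]
    b = B[None, :, :]
    both = (a > 0) & (b > 0) & mask
    m = np.count_nonzero(both & (a != b), axis=2).astype(np.int32)
    if conv.mode == "permissive_N":
        return m
    k = np.count_nonzero(((a == 0) | (b == 0)) & mask, axis=2).astype(np.int32)
    return np.where(m == 0, 0, m + k)


def barcode_space_size(length: int) -> int:
    """Number of possible barcodes of the given length (exact integer)."""
    return 4**length


def one_neighbor_probability(n_barcodes: int, n_variable: int = 15) -> float:
    """Probability that a given random barcode has another library barcode
    within Hamming distance 1 over the variable positions.

    A ball of radius 1 around a barcode contains ``1 + 3 * n_variable``
    sequences, so with ``N`` independent uniform draws the closed form is
    ``1 - (1 - (1 + 3 n_v)/4^n_v)^(N-1)``.
    """
    ball = 1 + 3 * n_variable
    p_hit = ball / float(barcode_space_size(n_variable))
    return 1.0 - (1.0 - p_hit) ** (n_barcodes - 1)


# ---------------------------------------------------------------------------
# codebook construction

@dataclass
class Codebook:
    """Accepted true barcodes with per-barcode rolony support."""

    entries: pd.DataFrame  # columns: barcode, support, absorbed_support
    fixed_positions: frozenset[int] = frozenset({9, 10})
    variable_length: int = 15
    _encoded: np.ndarray | None = field(default=None, repr=False)

    @property
    def barcodes(self) -> list[str]:
        return list(self.entries["barcode"])

    def encoded(self) -> np.ndarray:
        if self._encoded is None or self._encoded.shape[0] != len(self.entries):
            self._encoded = encode(self.barcodes)
        return self._encoded

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def _composition_ok(
    enc: np.ndarray,
    variable_mask: np.ndarray,
    max_identical: int = 13,
    min_variable_called: int = 13,
    max_n_run: int = 3,
) -> bool:
    """Composition limits for a codebook candidate (encoded barcode)."""
    called = enc > 0
    counts = np.bincount(enc[called], minlength=5)[1:]
    if counts.size and counts.max() > max_identical:
        return False
    if int(np.count_nonzero(called & variable_mask)) < min_variable_called:
        return False
    run = best = 0
    for v in enc:
        run = run + 1 if v == 0 else 0
        best = max(best, run)
    return best <= max_n_run


def _collapse_by_identity(barcodes: Iterable[str]) -> Counter:
    """Aggregate read barcodes into candidate counts by permissive-N-
    collapsed identity.

    Distinct strings are grouped greedily in descending count order: the
    most-supported unmerged string seeds a group of all unmerged strings
    compatible with it (zero mismatches under the N-matches-anything
    convention, all positions); the group's representative is its member
    with the most base-called positions (ties: higher count, then
    lexicographic), and only members also compatible with the
    representative merge into it — contradictory siblings (which disagree
    at a position the seed left uncalled) stay behind for later groups.
    A true barcode whose fully-called form was never read can therefore
    still surface as a candidate with one or two N positions, matching
    the composition limits codebook entries are allowed.
    """
    counts = Counter(barcodes)
    if not counts:
        return Counter()
    strings = sorted(counts, key=lambda b: (-counts[b], b))
    enc = encode(strings)
    n_called = (enc > 0).sum(axis=1)
    conv_all = HammingConvention(mode="permissive_N", exclude_positions=frozenset())
    n = len(strings)
    merged = np.zeros(n, dtype=bool)
    agg: Counter = Counter()
    for i in range(n):
        if merged[i]:
            continue
        open_idx = np.nonzero(~merged)[0]
        d_seed = distance_matrix(enc[i:i + 1], enc[open_idx], conv_all)[0]
        group = open_idx[d_seed == 0]
        # representative: most called, then most supported, then lexicographic
        rep = sorted(group, key=lambda j: (-n_called[j], -counts[strings[j]], strings[j]))[0]
        d_rep = distance_matrix(enc[rep:rep + 1], enc[group], conv_all)[0]
        members = group[d_rep == 0]  # always contains the seed (symmetry)
        merged[members] = True
        agg[strings[rep]] += sum(counts[strings[j]] for j in members)
    return agg


def build_codebook(
    read_barcodes: Sequence[str],
    fixed_positions: Iterable[int] = (9, 10),
    min_support: int = 3,
    max_identical: int = 13,
    min_variable_called: int = 13,
    max_n_run: int = 3,
    conv: HammingConvention | None = None,
) -> Codebook:
    """Build the codebook from assembled read barcodes.

    Candidates are aggregated by permissive-N-collapsed identity, sorted by
    support (descending, then lexicographic for determinism) and accepted
    greedily when they (a) have support >= ``min_support``, (b) satisfy the
    composition limits, and (c) have no already-accepted entry within
    Hamming distance 1.  A candidate rejected only for a 1-Hamming
    neighbour donates its support to that neighbour (reported in
    ``absorbed_support``), which keeps entry counts interpretable.
    """
    fixed_positions = frozenset(fixed_positions)
    if conv is None:
        conv = HammingConvention(mode="permissive_N", exclude_positions=fixed_positions)
    if len(read_barcodes) == 0:
        return Codebook(
            entries=pd.DataFrame(columns=["barcode", "support", "absorbed_support"]),
            fixed_positions=fixed_positions, variable_length=0,
        )
    L = len(read_barcodes[0])
    variable_mask = np.ones(L, dtype=bool)
    for p in fixed_positions:
        variable_mask[p - 1] = False

    agg = _collapse_by_identity(read_barcodes)
    cand = sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))
    enc_all = encode([b for b, _ in cand])

    accepted: list[int] = []
    support: list[int] = []
    absorbed: list[int] = []
    acc_enc = np.zeros((0, L), dtype=np.int8)
    for i, (b, c) in enumerate(cand):
        if len(accepted):
            # erroneous versions of an accepted barcode donate their support
            d = distance_matrix(enc_all[i:i + 1], acc_enc, conv)[0]
            near = np.nonzero(d <= 1)[0]
            if near.size:
                absorbed[int(near[np.argmin(d[near])])] += c
                continue
        if c < min_support:
            continue
        if not _composition_ok(enc_all[i], variable_mask, max_identical,
                               min_variable_called, max_n_run):
            continue
        accepted.append(i)
        support.append(c)
        absorbed.append(0)
        acc_enc = np.vstack([acc_enc, enc_all[i]])

    entries = pd.DataFrame({
        "barcode": [cand[i][0] for i in accepted],
        "support": support,
        "absorbed_support": absorbed,
    })
    return Codebook(entries=entries, fixed_positions=fixed_positions,
                    variable_length=int(variable_mask.sum()))


# ---------------------------------------------------------------------------
# matching

def match_to_codebook(
    queries: Sequence[str],
    cb: Codebook,
    max_distance: int = 2,
    chunk: int = 2048,
) -> pd.DataFrame:
    """Match query barcodes against a built codebook.

    Uses the strict-lookup convention with *no* excluded positions.  Each
    query is assigned the nearest entry when it is unique at distance
    <= ``max_distance``; queries tying >= 2 entries at the minimum distance
    are ``ambiguous`` (discarded downstream); the rest are ``unmatched``.
    """
    n = len(queries)
    out = pd.DataFrame({
        "query": list(queries),
        "barcode": pd.array([None] * n, dtype=object),
        "distance": np.full(n, -1, dtype=int),
        "verdict": ["unmatched"] * n,
    })
    if n == 0 or len(cb) == 0:
        return out
    E = cb.encoded()
    Q = encode(list(queries))
    for s in range(0, n, chunk):
        D = distance_matrix(Q[s:s + chunk], E, LOOKUP_CONVENTION)
        dmin = D.min(axis=1)
        for i in range(D.shape[0]):
            if dmin[i] > max_distance:
                continue
            hits = np.nonzero(D[i] == dmin[i])[0]
            gi = s + i
            out.iat[gi, 3] = "ambiguous" if hits.size > 1 else "matched"
            out.iat[gi, 2] = int(dmin[i])
            if hits.size == 1:
                out.iat[gi, 1] = cb.entries["barcode"].iat[int(hits[0])]
    return out


# ---------------------------------------------------------------------------
# read condensation after matching

def condense_reads(
    reads,
    matches: pd.DataFrame,
    jaccard_threshold: float = 0.8,
    max_n_run: int = 3,
):
    """Resolve multiply-claimed dots and collapse near-duplicate reads.

    ``reads`` is a sequence of :class:`axonmap.basecall.RolonyRead` aligned
    with ``matches`` rows.  Three steps: (1) a dot claimed by reads matched
    to more than one codebook barcode is blanked to N in every claimant;
    (2) reads violating the N-run limit after blanking are excluded;
    (3) within a matched barcode, reads whose dot sets have a Jaccard
    index >= ``jaccard_threshold`` collapse to the one with the most
    base-called digits.  Returns ``(kept_reads, kept_matches)``.
    """
    matched = [
        (r, matches["barcode"].iat[i])
        for i, r in enumerate(reads)
        if matches["verdict"].iat[i] == "matched"
    ]
    # step 1: blank conflicted dots
    dot_claims: dict[int, set[str]] = {}
    for r, bc in matched:
        for dot in r.dot_ids.values():
            dot_claims.setdefault(dot, set()).add(bc)
    conflicted = {d for d, owners in dot_claims.items() if len(owners) > 1}
    survivors = []
    for r, bc in matched:
        if conflicted:
            for cyc in [c for c, d in r.dot_ids.items() if d in conflicted]:
                r = r.blank_cycle(cyc)
        if r.max_N_run > max_n_run:  # step 2
            continue
        survivors.append((r, bc))

    # step 3: collapse similar rolony sets per barcode
    kept, kept_bc = [], []
    by_bc: dict[str, list] = {}
    for r, bc in survivors:
        by_bc.setdefault(bc, []).append(r)
    for bc, group in by_bc.items():
        sets = [frozenset(r.dot_ids.values()) for r in group]
        n = len(group)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                inter = len(sets[i] & sets[j])
                union = len(sets[i] | sets[j])
                if union and inter / union >= jaccard_threshold:
                    parent[find(i)] = find(j)
        groups: dict[int, list] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(group[i])
        for members in groups.values():
            best = max(members, key=lambda r: (r.n_called, -r.read_id))
            kept.append(best)
            kept_bc.append(bc)
    kept_matches = pd.DataFrame({
        "read_id": [r.read_id for r in kept],
        "barcode": kept_bc,
    })
    return kept, kept_matches
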