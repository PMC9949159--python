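# axonmap

Single-neuron projection mapping from *in situ* sequencing of axonal
barcodes.

## The problem

Barcoded anterograde tracing labels each neuron in an injection site with a
random nucleotide sequence expressed from a viral library. The barcode is
amplified into rolonies — sub-micron DNA nanoballs — that fill the soma and
travel into the axon. Cyclic *in situ* sequencing then reads one barcode
nucleotide per imaging cycle, in one fluorescence channel per base, so every
axonal rolony becomes a spatially localized, cell-identifying read. A single
experiment can thereby reconstruct the brain-wide projections of thousands
of individual neurons at once.

Turning those image stacks into per-neuron projection maps is almost
entirely a computational problem, and that computation is what this package
implements:

1. **Spot calling** (`axonmap.spots`) — rolony dots in 4-channel z-stacks:
   floor-subtracted projection (max over z minus the 3rd-lowest plane),
   z-score intensity correction from sampled local maxima, optional linear
   bleed-through unmixing, and a four-criterion detector with subpixel
   (quadratic) localization and a strict channel-purity ratio
   (2nd max / max < 0.95).
2. **Registration** (`axonmap.register`) — phase-correlation prealignment,
   gated least-squares affine/projective point-cloud registration to
   mid-sequencing reference cycles, and rolony-count-ordered tile
   stitching. Linear transforms only.
3. **Base-calling** (`axonmap.basecall`) — dots chained one-to-one across
   cycles within a 5-pixel gate, with a 3-cycle lookback so up to two
   consecutive lost cycles become `N` instead of breaking the read;
   disagreeing matches fork the read; reads with an `N`-run > 3 are
   discarded. Somata are base-called per pixel with phasing correction
   (subtract 50% of the previous cycle's dominant channel, 100% of the
   rest).
4. **Codebook** (`axonmap.codebook`) — the set of true barcodes inferred
   from the reads themselves: support ≥ 3 rolonies, composition limits
   (< 14 identical nucleotides, ≥ 13 of 15 variable positions called,
   `N`-run ≤ 3), and no two entries within Hamming distance 1. Reads are
   matched back under a strict lookup convention (distance cutoff 2,
   ambiguous matches discarded), then condensed so each rolony is counted
   once. Library-design fixed positions (9–10) are excluded from Hamming
   distances during construction but included at lookup.
5. **QC** (`axonmap.qc`) — error-prone barcode filters, per-cell count
   gates, secondary-infection exclusion (Hamming ball of radius 4),
   cross-field duplicate removal (< 25 μm), soma identification (≥ 80
   same-barcode counts within 100 μm), floating-rolony section detection
   and exclusion, and non-neural cell removal.
6. **Flatmap** (`axonmap.flatmap`) — a cortical (ML, AP, depth%) coordinate
   system built from any labeled volume: columns from each outer-boundary
   voxel to its nearest inner-boundary voxel, depth% along the column, and
   tangential axes from geodesic distances on the mid-cortical reference
   plate (PCA defines AP/ML; hemispheres processed independently).
7. **Cell typing** (`axonmap.celltype`) — CF vs IT from subcortical
   projections; ET vs CT by iterative 10-nearest-neighbour label
   propagation seeded from the dorsal/ventral bundle split in a
   striatal–thalamic fiber ROI; ITi vs ITc by contralateral counts (≥ 5).
8. **Projection statistics** (`axonmap.analysis`) — laminar depth profiles
   (1% bins) compared per cell with a permutation Kolmogorov–Smirnov test
   (1000 shuffles, different iff p ≤ 0.05), bootstrap group summaries,
   focal projection distance (mean of the shortest 33% of pairwise ML–AP
   distances), subsampling error curves, simulated retrograde tracing, and
   single-cell skeleton reconstruction (nearest-neighbour cluster merging,
   1000 μm edge cap).
9. **Synthetic data** (`axonmap.simulate`) — ground-truthed datasets with
   the statistical structure the pipeline assumes: four projection classes
   (CT, ET, ITi, ITc) with class-specific trajectories and laminar
   profiles, 17 sequencing cycles at 0.55 μm/pixel on 20 μm sections,
   per-cycle dropout, substitution errors, positional jitter, somatic
   phasing, floating rolonies and secondary-infection contaminants —
   plus an optional image renderer for the spot detector.

`axonmap.pipeline` wires steps 3–5 together on dot tables and carries the
ground-truth audits used for validation.

## Worked example

```python
from collections import Counter
from axonmap import celltype, pipeline
from axonmap.simulate import SimConfig, simulate_dataset

cfg = SimConfig(n_neurons=200, seed=0)          # default noise: 10% dropout,
ds = simulate_dataset(cfg)                      # 1% substitution, 0.5 px jitter
res = pipeline.run(ds.dots, cfg)

recall, precision = pipeline.codebook_recall_precision(
    res.codebook, ds.barcodes,
    [b for b in set(ds.rolony_truth.barcode) if b not in ds.barcodes])
print(f"reads assembled:    {len(res.reads)}")
print(f"codebook entries:   {len(res.codebook)}")
print(f"codebook recall:    {recall:.3f}")
print(f"codebook precision: {precision:.3f}")

cells = list(res.cells.values())
labels = celltype.classify_cf_it(cells)
print(f"projection classes: {dict(Counter(labels))}")
step1, final, n_iter = celltype.classify_etct(
    [c for c, l in zip(cells, labels) if l == "CF"])
print(f"ET/CT converged in {n_iter} iterations: "
      f"{dict(Counter(final.values()))}")
```

Output:

```
reads assembled:    10368
codebook entries:   203
codebook recall:    1.000
codebook precision: 1.000
projection classes: {'ITi': 100, 'CF': 47, 'ITc': 56}
ET/CT converged in 2 iterations: {'ET': 18, 'CT': 28}
```

The 203 codebook entries are the 200 neuron barcodes plus the 3 simulated
secondary-infection contaminants — all real barcodes present in the tissue,
which is why precision is 1.0; the QC stage (`qc.exclude_secondary`)
removes the contaminants downstream. The ET/CT counts cover the
thalamus-projecting CF cells the fiber-ROI propagation could label.

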