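# bindscape

Comparative analysis of transcription-factor (TF) variant binding and
single-molecule chromatin search kinetics.

Disease-associated missense variants in a TF's DNA-binding domain can
redistribute its genomic targets (losing native sites, gaining off-target
ones) and disrupt how individual molecules search the nucleus for those
sites. `bindscape` implements both halves of that comparison for
WT-vs-variant studies, together with a ground-truthed synthetic-data
generator so every stage can be validated as a parameter-recovery problem.
It is written for computational biologists working with per-allele binding
peak sets (e.g. from DamID or ChIP), protein-binding microarray (PBM)
intensities, and single-molecule tracking (SMT) data.

## What it computes

**Genomics arm**

- Base-pair Jaccard similarity between peak sets,
  `J = |A ∩ B| / |A ∪ B|` in bp, and the symmetric all-pairs matrix.
- A/B/C target partition of a WT-vs-variant pair: **A** = peaks bound only
  by WT (lost targets), **B** = bound by both (retained), **C** = bound only
  by the variant (off-target gains).
- GREAT-style "basal plus extension" peak-to-gene assignment (basal domain
  6.5 kb upstream / 2.5 kb downstream of the TSS, extended to the nearest
  neighbouring basal domain, at most 100 kb; peaks assigned by midpoint).
- k-mer motif scanning on both strands, flanking-base preference around the
  NKE core CACTT (high-affinity form **C**CACTT, low-affinity CACTT**T**),
  8-mer classes (high_NKE / low_NKE / HOX_like / other), Fisher tests of
  class proportions, and a dinucleotide-shuffle permutation Z-score.
- PBM 8-mer E-scores: the rank-based enrichment statistic
  `E = U/(n_f·n_b) − 0.5 ∈ [−0.5, 0.5]` over the brighter half of
  foreground (8-mer-containing) and background probes, reverse-complement
  collapsed, with the conventional E > 0.35 significance cut-off and
  WT-vs-variant landscape comparison.

**SMT arm**

- Spot detection (matched-filter GLRT at a 10^-6.5 per-pixel false-alarm
  rate, 7 px box, sub-pixel Gaussian refinement) and greedy
  mutual-nearest-neighbour linking (9 px radius, ≤2 gap frames, ≥5
  localizations).
- Fast modality (20 ms): per-track diffusion coefficients, MSD power-law
  fits `msd(t) = 4 D t^α + offset`, mobile/immobile split, the 3-state
  jump-distance mixture (bound / slow / fast fractions and diffusion
  coefficients with localization error fitted from the data;
  `p(r, t) ∝ Σ F_i · r/(2(D_i t + σ²)) · exp(−r²/4(D_i t + σ²))`),
  jump-angle anisotropy (reversal excess at 180°, jumps > 125 nm),
  confinement radii, and per-cell feature PCA.
- Slow modality (500 ms): residence times of the immobile population
  (per-track D ≤ 0.05 µm²/s), dwell-time survival curves, and one/two-
  component exponential decay fits yielding specific and non-specific dwell
  times and their fraction ratio.
- QC: per-cell IQR outlier removal; yeast-two-hybrid T2/T1 fluorescence
  ratios normalized to the WT bait and classified normal/perturbed/absent.

## Worked example

```python
from bindscape import (PeakSimConfig, simulate_peak_universe, classify_targets,
                       jaccard, DwellSimConfig, simulate_dwell_data,
                       survival_curve, fit_exponentials)

uni = simulate_peak_universe(PeakSimConfig(n_shared=50, n_lost=20, n_gained=10,
                                           planted_motifs=[("CACTT", 0.8, 2)],
                                           seed=1))
part = classify_targets(uni.wt, uni.variant)
print(f"Jaccard(WT, variant) = {jaccard(uni.wt, uni.variant):.3f}")
print(f"A (lost) = {len(part.a_peaks)}, B (retained) = {len(part.b_peaks)}, "
      f"C (off-target) = {len(part.c_peaks)}")

times = simulate_dwell_data(DwellSimConfig(seed=1))
fit = fit_exponentials(survival_curve(times), components=2, seed=1)
print(f"tau_long = {fit.tau_long:.2f} s, tau_short = {fit.tau_short:.2f} s, "
      f"frac_long = {fit.frac_long:.2f}")
```

prints

```
Jaccard(WT, variant) = 0.625
A (lost) = 20, B (retained) = 50, C (off-target) = 10
tau_long = 4.48 s, tau_short = 0.78 s, frac_long = 0.56
```

The partition recovers the planted universe exactly (20 lost, 50 retained,
10 gained peaks). The dwell fit recovers the simulated mixture (specific
dwell 5 s, non-specific 0.9 s, equal fractions) to within sampling noise at
n = 2000 tracks.

A `bindscape` command-line interface wraps the same functions:
`bindscape simulate`, `jaccard`, `partition`, `motifs`, `escore`, `track`,
`fastfit`, `slowfit`, `report`. Each pipeline run writes a `manifest.json`
with parameters and SHA-256 checksums of every artifact.

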