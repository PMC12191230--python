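# Methods

## Scope and design

`bindscape` implements a two-armed comparison of a wild-type TF against
missense variants: a genomics arm over binding peak sets, peak sequences
and PBM probe intensities, and an SMT arm over single-molecule image stacks
or trajectory tables. A synthetic-data module generates ground-truthed
inputs for every stage; all generators take an explicit seed and draw from
a single `numpy.random.default_rng` per call, so identical seeds give
bit-identical outputs. No global random state is used anywhere.

## Genomics arm

**Coordinates.** All intervals are 0-based half-open (BED). Overlapping and
bookended intervals are merged before set arithmetic, so Jaccard and the
A/B/C partition operate on disjoint intervals.

**Jaccard.** `J(A, B)` = overlapping bp / union bp, computed by a
two-pointer sweep per chromosome. Empty-vs-empty is undefined and raises;
in the all-pairs matrix an empty set flags its row/column as NaN rather
than reporting a silent 0.

**A/B/C partition.** A WT peak is *retained* (B) if it overlaps any variant
peak by at least `min_overlap_bp` (default 1 bp — the threshold is a free
parameter because any nonzero overlap is evidence of shared binding at
peak-call resolution), else *lost* (A); variant peaks overlapping no WT
peak are *off-target* (C). The B set is reported from the WT side; the
variant-side twins are kept for gene-level unions. Peaks are partitioned
first and gene sets derived second.

**Peak-to-gene assignment.** Each gene's regulatory domain is its
strand-aware basal domain (6.5 kb upstream, 2.5 kb downstream of the TSS)
extended on each side until the nearest other gene's basal domain or to at
most 100 kb from the TSS, whichever is closer. Extensions of neighbouring
genes may overlap in the gap between their basal domains, so a peak
midpoint there is assigned to both genes (the standard GREAT behaviour); a
base pair can belong to at most the two flanking genes' extensions plus any
overlapping basal domains. Peaks are assigned by midpoint, matching GREAT's
convention; any-overlap assignment would only add borderline peaks whose
midpoints sit in a neighbouring domain.

**Motifs.** Scanning is exact string matching of a k-mer and its reverse
complement, overlapping hits counted, `N` never matching. Flanking bases
around the NKE core CACTT are read on the strand of the match; edge
occurrences contribute only the flank they have, so the 5′ and 3′ column
sums may differ. 8-mer classes use a fixed substring precedence —
high_NKE (contains CCACTT) > low_NKE (contains CACTT) > HOX_like (contains
TAAT) > other — which makes the assignment total and strand-invariant. The
substring rule is a proxy for affinity-profile clustering; its precedence
resolves 8-mers containing multiple cores in favour of the more specific
core. Class proportions between two conditions are compared per class
(class vs rest) with two-sided Fisher exact tests (scipy). Motif
enrichment is a permutation Z-score of the total occurrence count against
per-sequence dinucleotide-preserving shuffles (rejection-sampled Eulerian
walks on the dinucleotide transition graph, preserving the exact
dinucleotide multiset and both end bases); this is an explicit
methodological substitution for exact motif-enrichment statistics, chosen
for transparency and seed-determinism.

**PBM E-scores.** For an 8-mer, foreground = probes containing it or its
reverse complement, background = the rest; probes containing `N` are
excluded from both groups. The brighter `ceil(n/2)` probes of each group
enter a Mann–Whitney pair count `U` (ties credit ½), and
`E = U/(n_f · n_b) − 0.5`. Being rank-based, E is invariant to any strictly
monotone intensity transform, which makes the pipeline insensitive to
upstream array normalization; the full-table computation shares one global
intensity ordering and reproduces per-8-mer calls exactly. Keys are
reverse-complement collapsed to the lexicographically smaller partner.
E > 0.35 is the conventional significance cut-off; its false-positive
control depends on per-8-mer probe coverage, so the generator emulates
universal-array coverage by implanting each mapped 8-mer into a
configurable number of probes (default 8), and the null-calibration test
uses 12,000 36-nt probes (mean coverage ≈ 10), where shuffled intensities
leave < 1% of 8-mers above 0.35. At low coverage (1–2 probes per 8-mer)
the E > 0.35 rule is anticonservative — as it is on real arrays with
under-covered k-mers.

**Probe intensity model.** Intensity = baseline + range × (max planted
affinity over contained 8-mers, either strand) + Gaussian noise. The max
rule (rather than a sum) keeps the planted landscape interpretable: a
probe's truth affinity is the strongest site it contains.

## SMT arm

**Detection.** The per-pixel test statistic is a zero-mean matched filter
(Gaussian kernel of the PSF width over the 7-px detection box) normalized
by a robust noise scale (1.4826 × MAD of the background-subtracted frame),
thresholded at the normal quantile of the false-alarm probability
(default 10^-6.5 per pixel) and additionally gated at 1.5× the local
background (the candidate-seeding threshold, exposed as a parameter since
its exact upstream semantics are not fixed); local maxima are refined by
Gauss–Newton least squares over (amplitude, background, centre) with the
PSF width held fixed, at most 50 iterations, 10^-2 termination tolerance,
and rejection if the centre moves more than 1.5 px. Monte-Carlo
calibration on pure Poisson-background stacks gives an empirical
false-positive rate ≈ 1.4× the nominal per-pixel bound (the residual
inflation comes from Poisson skewness at moderate backgrounds), within the
3× envelope asserted in the tests. The full multi-hypothesis deflation of
MTT-style detectors is deliberately simplified to this single-pass test;
the cost is reduced sensitivity for near-overlapping spots.

**Linking.** Greedy smallest-distance-first assignment between open track
ends and new localizations — equivalent to mutual nearest neighbours among
the unassigned — within a link radius of 9 px × pixel size, optionally
capped by 3σ of the expected per-frame displacement from a maximum
expected diffusion coefficient (1.5 µm²/s fast modality, 0.05 µm²/s slow).
Track ends persist ≤ 2 gap frames; tracks shorter than 5 localizations are
dropped. Duplicate (frame, x, y) localizations are an error.

**Jump-distance mixture.** For a molecule with diffusion coefficient D
observed with per-axis localization error σ at lag t, the jump length is
Rayleigh with scale² = 2(D t + σ²) (the observed displacement variance per
axis is 2Dt + 2σ², since independent errors at both endpoints contribute
2σ²). The 3-state fit pools jumps over lags 1–6 (excluding any window
spanning a gap-closed frame, where the true lag time is ambiguous),
evaluates each lag's empirical CDF on a 99-point equal-mass quantile grid,
and minimizes the summed squared CDF error with fractions parameterized by
stick-breaking (so they sum to 1 exactly), per-state D bounds
bound ∈ [1e-5, 0.1], slow ∈ [1e-3, 0.5], fast ∈ [0.2, 5] µm²/s, and
σ ∈ [0.005, 0.1] µm fitted from the data. Ten random multi-starts
(log-uniform in D) are polished and the best SSE kept. Because the
per-state bounds overlap, slot labels are not always identified: a
component with D ≈ 0.01 µm²/s fits identically from the bound or the slow
slot, and spurious ~2% components at the D lower bound can lower SSE
marginally by fitting noise. Fitted slot permutations of the best solution
are therefore refit and, among solutions within 1% SSE of the optimum, the
mass is reported in the slowest compatible slot. On the reference mixture
(F = 0.3/0.3/0.4, D = 0.01/0.15/1.0, σ = 0.035 µm, 5000 tracks at 20 ms)
recovery is within ±0.05 on fractions and ±20% on D across seeds.

**Per-track statistics.** Per-track D = ⟨r²⟩/(4Δt) − σ²/Δt over 1-frame
jumps, floored at 1e-6 µm²/s. MSD curves are time-averaged over all pairs
up to 90% of the track length; the power law `msd = 4 D t^α + offset` is
fitted with the offset constrained non-negative (it represents the 4σ²
noise plateau) from three deterministic starts (configured offset init 0.5,
log-log regression, first-lag slope) — without the non-negativity
constraint the offset/α trade-off drags single-track fits off scale. The
mobile/immobile split threshold defaults to 0.1 µm²/s, the upper edge of
the bound-state D range, exposed as a parameter. Jump angles between
consecutive displacement pairs, both above 125 nm, are folded to [0°, 180°]
(0 = forward); anisotropy = count(180° ± 30°)/count(0° + 30°). Confinement
radius is the maximum distance from the trajectory centroid (radius of
gyration available behind a flag). Per-cell feature means (median track D,
mean jump, median confinement radius, anisotropy, mobile fraction) are
standardized before PCA (SVD, deterministic sign: largest-magnitude loading
positive); constant features are dropped with a warning.

**Residence times.** Slow-modality track duration = (last − first frame
+ 1) × Δt; tracks with per-track D above 0.05 µm²/s are excluded as still
mobile. The survival function S(t) = fraction of durations ≥ t is
evaluated at the observed quantized times and fitted with 1- or
2-component exponential decays by multi-start least squares with uniform
weights. Times are referenced to the first observed point before fitting:
for frame-quantized data, S at k frames equals the continuous mixture
survival at (k−1) frames, so the shift removes the one-frame quantization
bias exactly. If the two fitted time constants fall within one time-grid
step the fit is flagged degenerate and collapses to the 1-exp solution.
Censoring at the acquisition limit is ignored (a documented
simplification: at 250 s versus a 5 s specific dwell the censored mass is
negligible); no photobleaching correction is applied by default, and an
optional correction dividing the rates by a user-supplied bleach rate is
off by default.

**Estimator precision.** At the reference conditions (n = 2000 tracks,
0.5 s frames, 5 s/0.9 s mixture, equal fractions) the survival fit is
unbiased (mean recovered 4.96 s / 0.88 s over 30 seeds) with spreads of
about 5% (tau_long) and 9% (tau_short) — close to the information limit:
an exact maximum-likelihood oracle on the same quantized data shows
occasional per-seed errors up to ~19%/26%. Tests therefore assert
distributional accuracy (medians, most-seeds bounds) rather than a hard
per-seed cap.

## Synthetic-data generator: what it does and does not emulate

The generator plants known structure so downstream modules are tested as
recovery problems: peak universes with disjoint shared/lost/gained peaks
and motifs planted on either strand; PBM tables from a planted affinity
landscape; trajectories from the 3-state model with static per-molecule
states (switching available via a rate matrix but off by default — the
jump-distance fit assumes per-trajectory states over its 6 lags);
bleaching as a geometric track-length distribution combined with
field-of-view exit; image stacks as Gaussian PSFs with Poisson shot noise
over Poisson background; bi-exponential residence times quantized up to
whole frames and censored; and two-time-point Y2H fluorescence where the
T2/T1 growth ratio scales with a planted interaction strength.

Not emulated: axial (out-of-focus) loss of fast molecules — consequently
the 3-state fit is validated without the defocalization correction, and on
real fast-modality data the fast fraction will be underestimated unless a
defocalization model is added; microarray hybridization chemistry and
spatial array artefacts; chromatin context (peak sequences are i.i.d.
background plus planted motifs); camera gain/EM noise (shot noise only).
Passing tests demonstrate correct recovery under the stated generative
models, not robustness to these unmodelled effects.

## Default study conditions

Fast modality 20 ms frames, slow modality 500 ms; pixel size 0.1 µm;
localization error 0.035 µm; reference mixture F = (0.3, 0.3, 0.4),
D = (0.01, 0.15, 1.0) µm²/s; bleach rate 2 s⁻¹ (mean track ≈ 25 frames at
20 ms); dwell mixture 5 s / 0.9 s, equal fractions, 2000 tracks, 250 s
acquisition limit; peak width 400 bp, GC 0.41; PBM probes 36 nt (default
60,000 per array, desk-scale analyses use 1–12 k with coverage-preserving
implanting). Problem sizes in the test suite (e.g. 5000 tracks for the
3-state recovery, 12,000 probes for the null calibration) were chosen as
the smallest giving stable recovery statistics.

## Y2H scoring

Each record's T2/T1 fluorescence ratio is divided by the WT bait's mean
ratio for the same prey; scores ≥ 0.75 are *normal*, < 0.25 *absent*,
otherwise *perturbed*. The thresholds are configurable defaults — the
underlying categorization is qualitative — and scores are invariant to
rescaling all fluorescence values. Records with T1 = 0 are flagged invalid
rather than scored.

## Known limitations

- Jaccard and partition operate on called peaks; peak calling itself is out
  of scope.
- The substring motif-class rule approximates affinity-cluster membership;
  8-mers matching none of the cores land in *other* regardless of affinity.
- The detection stage assumes an approximately flat local background within
  the detection box; strong background gradients inflate the false-alarm
  rate.
- Linking is greedy; dense fields with inter-molecule spacing comparable to
  the per-frame displacement will swap identities.
- The survival fit treats all tracks as fully observed (no censoring
  likelihood) and the 2-exp model assumes exactly two exchangeable-free
  populations.
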