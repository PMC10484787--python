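# Methods

This note documents the models, numerical choices, and design decisions
behind scarline, and what the simulation-based tests do and do not show
about real sequencing data.

## Coordinate and data model

All coordinates are 0-based half-open internally; conversion from 1-based
closed GTF-like input happens only at the format boundary. Genomes are tiled
into fixed-size windows per chromosome; a trailing remainder shorter than
the window size is kept and flagged rather than dropped, so a grid with
step = size covers every base exactly once. Tracks aligned to a grid use NaN
for missing values: zero coverage and "no data" are distinct quantities in
partition arithmetic, and missingness propagates rather than silently
becoming zero. Replication-timing strata are quartiles of the non-missing
track distribution ("early" = top quartile), a symmetric, scale-free cut
chosen because no numeric early/late boundary is canonical.

## Replication landscape

Initiation zones are placed per chromosome (evenly with jitter, or uniformly
at random), each with a firing efficiency in (0, 1]. Deterministic fork
direction is the all-zones-fire geometry: +1 immediately right of a zone
center, −1 immediately left, flipping at the termination midpoint between
adjacent centers (equivalently, the sign of the offset to the nearest
center). RFD is the efficiency-weighted expectation of that sign: the
probability that the nearest *fired* zone lies left minus the probability it
lies right, with equidistant fired zones counting as termination. This is
computed analytically by ordering zones by distance and accumulating
survival products over closer zones; a Monte-Carlo firing oracle checks it
in the tests. The default efficiency is 1.0 — the baseline condition in
which windows flanking a zone have |RFD| = 1, so oriented amplitudes carry
no RFD attenuation factor; sub-unit efficiencies exercise the probabilistic
machinery separately.

## Recycling and restoration model

Each window holds one nucleosome per 200 bp (canonical repeat length).
Per replication event the window's parental nucleosome complement `n` is
split binomially: the leading strand receives each parental nucleosome with
probability (1 + b)/2, where b ∈ [−1, 1] is the recycling bias (+ routes to
leading, − to lagging, 0 symmetric). The lagging strand receives the exact
remainder — parental histones are rerouted, never lost, and the
per-event identity `leading + lagging = n` is asserted in code and tests.
Unfilled positions receive new histones.

Inside a mark's domains, parental histones carry the mark with probability
π_p and new histones with

    π_n(t) = π_p · (1 − e^{−k t}) + a₀ (1 + c t) e^{−t/τ},

the first term being restoration toward the parental level at rate k (per
hour) and the second an optional transient "acetylation wave" on new
histones. The wave is parameterized so that a(0) = a₀ > 0 with a peak near
τ − 1/c: a difference-of-exponentials shape (zero at t = 0) cannot produce
a lagging-strand bias already present in nascent chromatin, which the
transient-acetylation phenomenology requires, so the linear-rise form is
used instead. Expected oriented partition in a fully marked domain is

    b (π_p − π_n)/(π_p + π_n),

which for a pure parental mark (π_n = π_p ρ) reduces to the closed form
b (1 − ρ)/(1 + ρ), and for a pure new-histone mark approaches −b.

Default mark kinetics (free parameters chosen for qualitative realism, not
estimates of any dataset): H3K27me3 k = 0.08/h and H3K9me3 k = 0.06/h (slow;
substantial asymmetry remains at 8 h), H3K4me3 k = 1.0/h (amplitude < 10 %
of A₀ by 3 h), H3K27ac π_p = 0.2 with a wave (a₀ = 0.5, τ = 2 h, c = 1/h)
peaking near 1 h. Scenario biases: wild type 0, leading-strand mutant +0.7,
lagging-strand mutant −0.3 (smaller magnitude, opposite sign), revertant 0.
The bias magnitudes are explicitly synthetic.

Read counts are drawn per strand around the marked-nucleosome densities,
with the forward strand corresponding to the leading daughter wherever fork
direction is +1 (windows with intermediate RFD mix orientations with
probability (1 + RFD)/2). Noise is negative binomial (gamma–Poisson,
dispersion 0.05) by default, with a Poisson option. The closed-form
verification grid uses the Poisson option deliberately: conditional on the
window total, the forward count is binomial, making the per-window partition
exactly unbiased, whereas NB sampling carries a small ratio bias
(≈ −α·p·(1−p²)/2 per window) that is irrelevant in practice but resolvable
at the precision of a 10-Mb mean.

## Partition, orientation, amplitude, kinetics

Partition is computed where F + R ≥ 10 reads (a variance floor, exposed as a
flag) and is missing otherwise. Profiles collect partition values at signed
distances from zone interval midpoints (the anchor choice), excluding
windows with |RFD| < 0.5 (ambiguous fork direction; exposed). Replicate
profiles are computed per replicate and then averaged. The profile reports
raw mean partition per signed-distance bin — the familiar antisymmetric
figure shape — while the scalar asymmetry amplitude orients each window by
the sign of its RFD (identical to the sign of its distance for all windows
passing the RFD filter) before averaging over windows outside a 1-kb inner
exclusion. Orienting by fork direction rather than by geometric side makes
the amplitude exactly invariant under the joint relabeling F↔R plus
RFD → −RFD, which is the testable sign-convention contract. The 95 % CI
bootstraps zones, the independent units.

Kinetics are fitted on amplitude summaries (not per window, keeping the
inverse problem well-posed at desk scale) by least squares from several
starts: `exp_decay` fits A(t) = A₀ e^{−kt}/(2 − e^{−kt}) (the closed form
with ρ = 1 − e^{−kt}); `wave_plus_decay` adds the simulator's wave term.
Non-monotone data under `exp_decay` still fit but set a lack-of-fit flag
when the relative residual RMS exceeds 15 %.

## Spike-in comparison and the NB test

Scale factors are spike_reference/spike_sample (reference = first sample by
default; only ratios matter and the factors are recorded for audit).
Normalization is multiplicative, so jointly rescaling one sample's genome
and spike counts is a no-op (tested). Bins are stratified by reference-
condition peak overlap (≥ 1 bp by default, exposed — the minimum overlap is
not canonical) and replication-timing quartiles; strata compose as boolean
masks and BH runs within each stratum separately.

The differential test models per-bin counts as NB with log link, spike-in
size factors as offsets, and a condition indicator; it is fitted by IRLS
vectorized across bins. Dispersion: per-bin method of moments with the
n_g/(n_g − 1) correction for fitted group means (without it the estimate is
biased low by a third at 3 + 3 replicates), a linear trend α(m) = a₀ + a₁/m
fitted on the *unclipped* estimates (clipping negatives first would bias
the trend upward), and shrinkage toward the trend with weight
n_prior/(n_prior + df_resid), n_prior = 10. The Wald statistic is referred
to a Student t with effective df = (n_prior + df_resid)²/df_resid, the
variance-based df of the shrinkage estimator given a trend fitted across
thousands of bins: pooled null simulations show the plain normal is 2–3×
anticonservative at p < 10⁻³ and the naive df = n_prior + df_resid is an
order of magnitude conservative there, while the effective-df t is
calibrated at every threshold checked. Reported log2 fold changes use a
0.5-pseudocount moderation on normalized means; classes are gain/loss/ns at
FDR 0.1 for bins (0.01 for promoter-level calls). All-zero bins are excluded
and counted in the audit log.

A mutant-significant feature is "rescued" when it is no longer significant
versus wild type in the revertant, or its revertant fold change is below
50 % of the mutant fold change in magnitude — an explicit, flagged rule.

## Repeats

Fractional 1/n multimap assignment is deterministic and mass-conserving;
shares are accumulated as exact rational fractions so that
unique + multi + unassigned equals the read count identically. Alignments
overlapping no annotated copy go to an explicit unassigned sink. The
multimapping-fraction denominator is all mapped reads in the library (not
just repeat-overlapping reads) — a flagged choice. Subfamily differential
tests reuse the NB core with library-size offsets on total (unique +
fractional) mass, with a unique-only mode for sensitivity analysis;
significance requires both FDR < 0.01 and |log2FC| > 0.58.

## Enrichment layer

Odds ratios are cross-product ratios with a Haldane–Anscombe +0.5 correction
when a cell is zero (p-values always from the exact test on the uncorrected
table). Chromatin states use fixed-precedence rules (bivalent > active >
polycomb > heterochromatic > quiescent) with per-mark "high" thresholds
defaulting to the upper tertile on the analyzed feature set — a scale-free
substitute for an external chromatin-state resource. Clustering is Ward on
Euclidean distance of column-z-scored changes (constant columns dropped with
a warning); scipy's deterministic linkage ordering provides the tie rule.
Gene–repeat proximity anchors at the strand-aware TSS (5′ end) with a 10-kb
radius, both exposed.

## Simulator defaults and study conditions

Binned ChIP baseline occupancy is Gamma-distributed with mean 250 reads per
5-kb bin (40 M-read libraries over 5-kb bins overlapping broad-mark peaks at
3–5× enrichment land in the 200–370 range), 3 replicates per condition,
2.5 % spike-in, NB dispersion 0.05, and ±15 % log-normal depth jitter.
Repeat simulations use ~200 subfamilies at ~400 reads each with per-subfamily
multimapping rates in [0.2, 0.9], planted 2× losses in 10 % of subfamilies,
and RNA log-fold changes coupled to PTM changes with coefficient −1 plus
noise. Promoter-state fixtures apportion class counts deterministically
(largest remainder) with each mark's high-signal share exactly one third, so
the tertile threshold falls in the gap between well-separated signal modes
and the recovery metric measures the assigner rather than class-count
sampling noise. Problem sizes in the test-suite and acceptance runs (10-Mb
and 5-Mb toy chromosomes at 1-kb windows, 2,000 bins, 50–100 replicate
simulations) are desk-scale choices that keep every experiment re-runnable
in minutes.

A single top-level seed drives everything; each stochastic operation derives
an independent child stream from (seed, operation name, labels) via CRC-32
hashing into a SeedSequence, so outputs are reproducible yet streams are
independent across operations and samples.

## What passing tests do and do not show

The simulator emulates the *statistical structure* of the assays: strand
asymmetry with fork-direction geometry, restoration kinetics, spike-in
scaling, overdispersed counts, multimapping mass, planted states and
couplings. It does not emulate mappability artifacts, GC and fragment-length
biases, peak-calling uncertainty, EdU labeling efficiency, cell-cycle
heterogeneity, or sequence-level read placement. Passing tests therefore
demonstrate that the statistics are correctly implemented and calibrated
under their stated models — not that any particular biological effect size
would be recovered from real libraries. Quantities printed in published
figures from real data (counts of differential genes or promoters, rescue
tallies, specific odds ratios) depend on deposited sequencing data and are
intentionally not asserted anywhere in this package.

## Known limitations

- The NB Wald test is anticonservative if dispersions are grossly
  misspecified away from the fitted trend family (a₀ + a₁/mean).
- The analytic RFD assumes independent zone firing and nearest-fired-zone
  replication; real fork speed heterogeneity and dormant-origin activation
  are out of scope.
- The rescue rule's 50 % magnitude criterion is a convention; rescue
  fractions shift with it (it is a flag).
- `wave_plus_decay` with four parameters on four time points is exactly
  determined; with real replicate noise, more chase points are advisable.
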