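# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic cohorts do and do not show about
real methylation-array data.

## Synthetic cohort model

A cohort is a CpGs × samples matrix of beta values with four sample groups:
the translocation-positive cases (`BCL3`), two other-CLL control groups
(`CLL_U` without an IG translocation, `CLL_IGTRANS` with a different IG
translocation), and a plasma-cell-like group (`PC_LIKE`).

**Baseline methylome.** Each CpG receives a chromatin state
(heterochromatin / active / other) and a methylation-dynamics module label
in {1..13, none}; modules 8, 9 and 13 are heterochromatic by a fixed rule
table, mirroring the late-B-cell-differentiation modules in which
heterochromatic demethylation concentrates. Baseline (control) means follow
the usual bimodal methylome shape: heterochromatic CpGs draw from
U(0.60, 0.95), active CpGs from U(0.05, 0.30), the rest from U(0.15, 0.85).

**Planted effects.** `n_hypo` hypomethylated and `n_hyper` hypermethylated
truth CpGs are planted at exactly `delta_beta` (default 0.35, satisfying
the |Δβ| ≥ 0.3 regime of the discovery analysis). Hypo CpGs are sampled
90% from heterochromatin-state CpGs in modules {8, 9, 13} and 10%
elsewhere, so module/state enrichment of a recovered DMC set is a
construction consequence, not an accident. Baselines that leave no room
for the planted shift are moved into range with a logged warning. The
plasma-cell-like group shares 80% of the hypomethylation effect — enough to
resemble the cases at heterochromatic CpGs without duplicating them.

**Purity and noise.** Observed means are
`purity · tumor + (1 − purity) · baseline` with per-sample purity uniform
on `purity_range`; measurement noise is Beta-distributed with the planted
mean and concentration `precision` (mean·precision, (1−mean)·precision).
The Beta family respects the [0,1] support and `precision → ∞` recovers
the noiseless identity used by the tests. The biological/technical variance
split of real arrays is not identified by any published number we rely on,
so `precision` is an explicit free parameter; 50 (beta SD ≈ 0.07 at
β = 0.5) is the default cohort condition and 100 the "high precision"
regime of the recovery benchmarks.

**Follow-ups** copy a case profile plus independent N(0, `within_noise`)
noise (default 0.02), which makes within-patient correlation exceed
between-patient correlation in expectation — the qualitative shape of the
longitudinal-stability analysis. The printed follow-up test statistics of
the real cohort depend on unpublished per-pair correlations and are treated
as form anchors only; the package recomputes the same statistics (Welch t,
Hedges g with CI) on its own cohorts.

**What the generator does not emulate:** probe-type chemistry and IDAT
intensities, batch/plate effects, cell-composition heterogeneity beyond a
single purity scalar, spatial correlation along the genome, and the exact
CpG content of the published epitype/epiCMIT/classifier signatures. Passing
tests therefore demonstrate correctness of the algorithms under the stated
statistical structure, not real-data performance.

## Copy-number calling

Per-probe log2-ratio-like values are normalized by subtracting the
per-probe median of ≥ 3 reference samples, then segmented per chromosome by
binary changepoint splitting that minimizes within-segment squared error; a
split is accepted while it reduces the cost by more than
`6 · log(n) · σ²`, with σ estimated robustly from first differences
(median|diff| · 1.4826/√2). `min_probes` (default 10) bounds segment size;
focal events smaller than that are out of scope. Segment state uses the
strict rule gain iff median > 0.1, loss iff median < −0.1 — a median of
exactly 0.1 is neutral. Negating all ratios exactly swaps gains and losses.
The segmentation algorithm and reference-set composition are configuration,
since only the median cutoff is an externally fixed rule.

## Epitype and epiCMIT

Epitype assignment is nearest centroid by Euclidean distance over a
signature CpG set (Euclidean chosen as the simplest defensible metric; the
published classifier's internals are not reproduced). Samples with purity
below 0.60 are withheld as "unclassified"; exactly 0.60 is classifiable
(the rule is strict "below"). Purity is an input from the sample sheet —
estimating it is out of scope. Distance ties break by the fixed order
n-CLL < i-CLL < m-CLL and are flagged. The epiCMIT score is
`max(mean β over hyper-clock CpGs, mean (1−β) over hypo-clock CpGs)`,
monotone in both clock sets; the published clock CpG lists are replaced by
synthetic sets in tests.

## Differential methylation

Per-CpG Welch t on beta values (the per-CpG test family is not externally
fixed; an M-value alternative would behave similarly at these effect
sizes), BH-FDR over *all* tested CpGs, and calls requiring both q < 0.01
and |Δβ| > 0.3. Δβ is case − control, so case hypomethylation is negative.
CpGs constant in both groups get p = 1. Enrichment uses the two-sided
Fisher exact test (p by hypergeometric probability-mass summation, OR =
ad/bc with an ∞ flag for empty denominators) with BH-FDR across
categories.

## Classifier

Pipeline defaults: top 10,000 CpGs by variance (ties lexicographic by CpG
id); k-means with k = 100 over CpG profile vectors using a single seeded
k-means++ initialization (deterministic and fast at desk scale; the
representative of each cluster is the medoid); minority oversampling by
convex interpolation of random minority pairs, applied to the training
fold only (leakage-safe placement is mandatory); a 500-tree random forest
with unbounded depth; a single stratified held-out split at
`test_fraction = 0.25`. k, the model family, the sampling technique and
the split protocol are not externally fixed and are all exposed as
configuration.

Attribution is exact decision-path attribution: along each tree's root-to-
leaf path, every split credits its feature with the change in node case
probability, so `base value + Σ attributions = P(case)` holds to machine
precision per sample (the local-accuracy property the tests assert at
1e−6). The reduced signature takes the 20 features with largest mean
|attribution|; each CpG's direction is the sign of the correlation between
its beta values and its attributions, and a reduced forest is refit on the
same training fold and evaluated on the same held-out fold. Classification
uses P(case) ≥ 0.5 as the case boundary (documented: exactly 0.5 is case).

## Junction annotation

Coordinates are 1-based inclusive. "Upstream of BCL3" is the centromeric
side, the low-coordinate side on 19q; the containing feature is the
innermost annotated span (introns beat genes), or the nearest feature for
intergenic positions. RSS scanning uses the canonical heptamer `CACAGTG`
and nonamer `ACAAAAACC` with spacer 12±1 or 23±1 and a total mismatch
tolerance of 1, on both strands; no published scoring matrix is fixed, so
the consensus with minimal slack is the default and all three knobs are
configurable. Insert/microhomology quantification finds the maximal left-
flank suffix and right-flank prefix matches into the junction: a gap
between them is the untemplated insert, an overlap is microhomology
(present once at the join), and exactly one of the two can be nonzero.
Mechanism inference: CSR if the IGH-side breakpoint lies in a switch
region; V(D)J if it lies in a J/D gene with an RSS heptamer within 25
bases of the junction point and a nonzero untemplated insert; CSR takes
precedence; anything else is "undetermined". The containment rule is an
operationalization — published mechanism assignment is partly implicit —
and is flagged as such in outputs by keeping the true and called mechanism
side by side where truth is known.

The bundled hg38-derived coordinate table (BCL3 region with CEACAM16,
CBLC, NECTIN2; IGH switch regions in locus order plus IGHJ6/IGHD1-7) uses
approximate public-annotation spans and is regenerable from genome
browsers; tests run on fully synthetic loci so no download is needed.

## Problem sizes and determinism

The standard classifier surrogate uses 80 cases vs. 150 pooled other-CLL
controls over 20,000 CpGs with 1960 + 25 planted DMCs — the real cohort's
sample structure at a reduced array scale (the real analysis covers
441,870 quality-passing CpGs). DMC-recovery benchmarks run 50 simulations
of 2,000 CpGs at 80/32 samples with precision 100 and purity 1 (the
filters apply to observed Δβ, so purity mixing is a property of the
classifier surrogate, not the discovery benchmark); CNV benchmarks run 100
genomes of 2,000 probes with a +0.15 chr12 shift at probe noise SD 0.03;
junction benchmarks run 100 CSR + 100 V(D)J junctions. One master seed
derives per-component streams via fixed offsets; every stage is
byte-identical across repeated runs with the same seed.

## Known limitations

Beta-scale Welch tests lose a little power near the boundaries compared to
M-values; the oversampler interpolates without nearest-neighbour
restriction, which can blur multi-modal minority classes; binary
segmentation is greedy and may misplace breakpoints of adjacent opposite
shifts; RSS detection with tolerance 1 will miss degenerate physiological
RSSs; and none of the published signature CpG identities are reproduced —
only the procedures that produced them.
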