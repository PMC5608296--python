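# Methods

## The analysis problem

Bead-array expression profiles of purified intestinal epithelial cells
(IECs) from duodenal biopsies are compared between active celiac disease
and clinical controls, with tiny groups (four per arm at the screening
stage). Two features dominate the statistics: the IEC preparations carry a
small admixture of intraepithelial lymphocytes (IELs), and at n = 4 vs 4
the p-value of any rank test is confined to a handful of discrete values,
the smallest being 2/70 ≈ 0.0286. The pipeline addresses both explicitly
rather than pretending to asymptotics.

## Contamination model and correction

The observed disease-arm profile is modelled as a two-population convex
mixture per sample *j*:

    observed[g, j] = (1 − f_j) · pure[g, j] + f_j · iel_profile[g] + ε

with additive background noise ε (the source of occasional negative
background-subtracted signals). Because the T-cell markers CD3D, CD3G,
CD2, CD7, CD8A and CD247 have zero epithelial expression, each marker's
IEC:IEL signal ratio estimates f directly. Per-marker ratios (IEC signal
pooled over samples by the median, clamped at 0) are pooled by their
median — robust to a single cross-hybridising marker; a per-sample
summary (median over markers within each sample) is reported alongside,
since the observed 5–10% spread may sit on either axis. The IEL reference
profile is the per-gene median across IEL samples.

Correction subtracts `f · iel_reference` gene-wise and clamps negatives
to zero; the default is the fixed f = 0.10 applied in the original
analysis. Note that plain subtraction of a convex mixture leaves the
epithelial component scaled by (1 − f): this is immaterial for
median-ratio statistics when both arms are treated alike, and otherwise a
conservative ≤10% attenuation of case signal. `rescale=True` divides by
(1 − f) and inverts the mixture exactly — the package's own extension,
used where exact restoration of the pure profile matters. Genes absent
from the IEL reference pass through unchanged. The generator plants
admixture only in the active-disease arm (inflamed mucosa is
lymphocyte-rich), so the driver corrects the control arm at f = 0 by
default; a `ctrl_fraction` knob covers designs where both arms need it.

## Exact Mann–Whitney test

Per gene, pooled values receive mid-ranks; U is computed from the group-1
rank sum. The two-sided p-value is twice the smaller one-sided tail of the
exact permutation distribution of the rank sum over all C(n₁+n₂, n₁)
assignments, capped at 1 — the conventional exact two-sided definition,
which reproduces the printed 0.028 (= 2/70 truncated; `format_p`
truncates rather than rounds for display, full precision is kept in
machine output). The null distribution is obtained by a counting recursion
over the doubled-rank multiset (doubling makes mid-ranks integers), so
ties get their exact conditional distribution; counts stay below 2^53 for
the combined sizes enumerated (≤30), keeping float64 arithmetic exact.
Beyond 30 the tie-corrected normal approximation takes over. The
distribution is cached per tie pattern, which makes genome-wide scans
cheap: continuous data share one pattern.

## RQ, calibration and selection

RQ is the ratio of group medians after two rules for background-subtracted
arbitrary-unit data: negative signals → 0 before medians (applied to both
arms — corrected case negatives are already clamped by the correction
stage, so in practice the rule bites on controls, matching the original
bookkeeping); a control median of exactly 0 → 0.01 to keep the ratio
finite. Genes with RQ < 1 stay in the table flagged `upregulated=False`;
the analysis focuses on upregulation. An optional Benjamini–Hochberg
column can be added for reference; it never gates selection — the
calibration step is the study's surrogate for multiplicity control.

Calibration scans a cut-off grid (default 1.0–3.0 by 0.1, bracketing the
operative 1.4 and 1.8 values) and reports, per cut-off c, the fraction of
genes with RQ > c that are significant at α, choosing the smallest c whose
fraction exceeds α. The denominator is cumulative (genes above the
cut-off) because the final criteria are themselves cumulative thresholds;
a banded mode is available. **Caveat**: because a large observed median
ratio and group separation are positively correlated, the conditional
fraction can exceed α at stringent cut-offs even on fully null data
(measured ≈6.5% at c = 1.2 under the generator's homoskedastic log-normal
noise) although the marginal significant fraction is exactly 2/70 ≈ 2.86%.
A chosen cut-off therefore indicates enrichment relative to the
unconditional chance level, not a calibrated false-positive rate at that
cut-off; heavier-tailed real-data noise weakens the correlation and is the
likely reason the original data crossed 5% only above RQ 1.4.

Selection applies the criteria literally — case median ≥ 60 AU, RQ ≥ 1.8,
p ≤ α, RQ ≥ 1 — and reports an audit count after each successive filter
(expressed → significant → RQ → signal).

## qPCR quantification

The standard curve is ordinary least squares of mean CT on log10(amount),
needing ≥3 distinct dilution points; efficiency = 10^(−1/slope) must fall
in (1, 2.2]. One unit (U) of 18S rRNA is the amount in 10 pg of the
standard; inverting the curve converts a CT to units, epithelial cells
carry ≈1 U each (cell-yield estimation), and samples at ≤25 U per
reaction are excluded. Replicate CTs are summarised by the arithmetic
mean (the customary choice; the source protocol does not state one).
ΔCT = CT(gene) − CT(18S) within a sample; ΔΔCT subtracts the per-gene
median ΔCT of the reference group, so the reference median RQ is 1 by
construction; RQ = 2^(−ΔΔCT) with the conventional fixed efficiency of 2
in the exponent — the curve-derived efficiency is reported but not
applied (no Pfaffl correction).

Group tests run on ΔCT rather than RQ to avoid exponentiation-induced
skew; ranks and t statistics are invariant to that affine choice. Designs:
exact Mann–Whitney (two groups), classical pooled-variance two-sided t,
and one-way ANOVA with Dunnett-style many-to-one contrasts. The Dunnett
familywise adjustment is a seeded **parametric Monte-Carlo max-|t|** null
(default 100,000 resamples): standard-normal groups are drawn at the
observed sizes and every contrast recomputed with the resampled pooled
MSE. The statistic is pivotal under normality, so with a single treatment
the simulated null is exactly Student-t with N − k degrees of freedom and
the adjusted p converges to the closed-form two-sample t p-value; with
several treatments it agrees with the tabulated Dunnett distribution to
Monte-Carlo error (cross-checked in the tests). Adjusted and unadjusted
p-values come from the same resamples, so adjusted ≥ unadjusted holds by
construction; both use the (1 + exceedances)/(B + 1) estimator, so no
reported p is exactly 0.

## Concordance and diet response

An array-selected gene is *confirmed* when its qPCR active-vs-control
comparison has p ≤ α **and** the active-arm median RQ exceeds 1 —
direction is required so an inverted hit cannot count as confirmation.
The summary percentage (rounded half-up to an integer, e.g. 25 of 33 →
76%) is taken over genes actually tested; selected genes without qPCR
data are listed as untested, not failed. Diet response is classified from
the treated-vs-control comparison: `normalized` (p > α),
`persistent_elevated` (p ≤ α, RQ > 1), `decreased_below` (p ≤ α, RQ < 1);
a significant result at RQ exactly 1 is degenerate and reported as
normalized with a warning. The symmetric rule is this package's
formalisation; the decreased direction is tested with the same two-sided
statistics as the elevated one.

## Synthetic data: what it emulates, what it does not

Baselines are log-normal in AU (natural-log mean 3.0, sd 1.6), chosen so
the median signal is ≈20 AU, ~55% of genes clear the 15 AU expressed cut
(echoing roughly 10,000 expressed of 18,000 probed) and the range spans
below 1 to above 10,000 AU. Within-group variation is multiplicative
log-normal at CV 0.25 (AU signals are non-negative and skewed; the real
within-group variance is not published, so it is an exposed parameter).
Planted upregulation multiplies a random minority of genes (default 5%)
in the disease arm by factors drawn from a configurable range;
`de_min_baseline` restricts planting to well-expressed baselines when the
scenario calls for effects the signal criterion can see. Markers are
appended with zero epithelial expectation and high IEL expectation
(log-normal around ≈1,800 AU), so they can never overlap the planted set.
Admixture defaults to fractions evenly spaced over 5–10% across case
samples, the estimated contamination range of the motivating study.
Additive Gaussian background (sd 2 AU) is applied after mixing and
negatives are retained in the generated files — zeroing them is
downstream bookkeeping. The qPCR generator shares fold changes with the
array truth when asked, uses CT = ct_ref − log_E(amount) with triplicate
normal noise, and anchors a 2-fold 18S dilution series at 10 pg = 1 U.

Not emulated: probe-level intensities, bead replicates and cubic-spline
normalisation (simulation starts at normalised signals); heavy-tailed or
sample-correlated noise; more than two mixing populations; amplification
inhibitors or melt-curve artefacts in qPCR. Passing tests therefore show
the pipeline's logic is correct under its stated model, not that the
model captures every pathology of real arrays.

## Problem sizes and numerical choices

Test and acceptance runs use 400–6,000 genes for simulation checks and
10,000 genes for the all-null chance-level check — sizes at which the
Monte-Carlo targets (±0.02 on admixture recovery, ±0.01 on the Dunnett
degeneracy at 100,000 resamples, the 2/70 chance level within ±0.6
percentage points) are comfortably resolved; the whole suite runs in
seconds. Exact-test enumeration is capped at combined n = 30. Degenerate
inputs are handled explicitly: all-identical values give p = 1 flagged
degenerate; an empty calibration stratum reports a missing fraction; an
empty expressed set yields empty outputs with an advisory, not an error.
All randomness flows through `numpy.random.default_rng(seed)`; every
generator and Monte-Carlo routine takes an explicit seed, and identical
seeds give bit-identical outputs, including after TSV serialisation.
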