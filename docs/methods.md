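# Methods

## Scope and data model

`csfpre` analyses protein-level abundance tables from four experiment
designs probing pre-analytical effects on the CSF proteome: (i) whole-blood
spike-in at two levels against an unspiked reference, (ii) a centrifuged /
not-centrifuged pair of equally spiked aliquots, (iii) a seven-point
rostro-caudal gradient (RCG) series quantified against a pooled reference
channel, and (iv) paired plasma/CSF samples from several patients.

All stages speak `AbundanceMatrix`: linear-scale, non-negative abundances
with explicit `NaN` missing values and per-sample role metadata. Missingness
propagates — a ratio with a missing operand is missing — and nothing is
imputed; proteins simply drop out of downstream counts, mirroring the
quantified-in-all-experiments filters typical of such studies. Readers are
column-name translations over tab-separated exports; no vendor binary format
is touched.

## Contamination model

A sample with blood volume fraction *f* is modelled as a two-phase mixture.
Writing *c* for the clean-CSF concentration, *r* for the equal-volume
plasma/CSF concentration ratio, *caf* for the fraction of the whole-blood
amount carried by cells/platelets and *p* for the cellular enrichment
relative to *c*, the expected abundance is

    a(f) = (1 − f)·c + f·[(1 − caf)·r·c + caf·p·c·(1 − removal·centrifuged)]

so the fold change versus the reference is FC(f) = a(f)/c, strictly
increasing in both *f* and *r* and equal to 1 at *f* = 0. Centrifugation
before freezing removes a fraction `removal` (default 0.95) of the cellular
payload only — plasma-phase proteins are untouched, which is exactly why the
centrifugation comparison isolates the cell-associated
(hemoglobin/carbonic-anhydrase) class.

The inverse model estimates an unknown *f* from observed directional fold
changes as the median of fᵢ = (FCᵢ − 1)/(rᵢ − 1) over proteins with
rᵢ ≥ 50 (floor excludes mixed-origin proteins with intrathecal synthesis)
and FCᵢ > 1. The median, not the mean, is used for robustness to
interference and to proteins whose CSF level is partly brain-derived;
cell-associated accessions should be excluded by the caller since their
fold change is centrifugation-dependent. The estimate carries the
interquartile range of the per-protein fᵢ as its dispersion. Because the
technical noise factors are mean-1 log-normal, the ratio of two noisy
abundances has median 1 and the median-based estimator is median-unbiased;
with 100 eligible proteins at 20% CV the estimate lands within 20% relative
error essentially always (the test suite checks ≥ 95 of 100 seeded runs at
both 0.5% and 2%).

## Classification rules

Fold-change thresholds 1.5 (affected) and 1.2 (unaffected) with the
uncertain band between; the gradient classifier additionally requires
linearity, R² of the ordinary least-squares fit of ratio against the integer
point index 1..7 (not collected millilitres: the designs index points, and
no volume-weighted fit is defined). The full rule set:

| experiment      | affected            | uncertain                         | unaffected                  |
|-----------------|---------------------|-----------------------------------|-----------------------------|
| spike-in        | any level FC ≥ 1.5  | otherwise                         | both levels FC < 1.2        |
| centrifugation  | FC > 1.5 (strong if > 10) | 1.2 ≤ FC ≤ 1.5              | FC < 1.2                    |
| gradient        | R² > 0.7 and FC ≥ 1.5 | R² > 0.7, FC < 1.5; or 0.3 ≤ R² ≤ 0.7, FC > 1.2 | 0.3 ≤ R² ≤ 0.7, FC ≤ 1.2; or R² < 0.3 |

Boundary conventions, fixed here because the printed inequalities leave
exact ties open: spike-in FC exactly 1.5 → affected and exactly 1.2 →
uncertain; centrifugation FC exactly 1.5 → uncertain (strictly-greater
rule); R² exactly 0.7 or 0.3 falls in the middle band; FC exactly 1.2 with
mid R² → unaffected. These make every rule a total function, verified by
property tests. Spike-in classification is directional (increases only);
a ≥ 2-fold decrease at the high level sets a separate `suppressed` flag —
ion suppression by the added blood is a different phenomenon from
contamination enrichment, so it is never a category. Degenerate constant
ratio profiles have SS_tot = 0 and are assigned R² = 0 (a constant protein
cannot exhibit a gradient). Cross-platform categories merge by
affected + uncertain = affected, unaffected + uncertain = unaffected,
affected + unaffected = uncertain, with not-evaluable as identity; the
merge is commutative and idempotent (exhaustive 4×4 test). Proteins on the
immunoaffinity depletion list are dropped before classification in
depleted-workflow data.

## Gradient and volume model

Plasma-derived protein concentration is taken as linear in collection
position, from `end_to_end_fc` (default 1.6) at the lumbar end to 1 at the
ventricular end of a `total_volume` (default 45 mL) column. Collecting only
the first *v* mL yields a mean concentration fc + (1 − fc)·v/(2V); the
reported volume effect is its difference from the full-pool mean (fc + 1)/2,
×100, expressed relative to the ventricular-end concentration — this
convention reproduces the published arithmetic (1.6-fold gradient → ≈ 30%
for 1 mL vs 45 mL); relative-to-pooled-mean is available as an option
(22.6% for the same inputs). For clinically common 5–20 mL collections the
model gives 26.7% down to 16.7% (ventricular-end convention), a wider span
than the ~10–15% sometimes quoted for that range; no single formula derived
from the 1.6-fold linear gradient reproduces that narrower figure, and we
report the model value rather than reconcile it.

## Plasma/CSF ratios

Per-protein per-patient ratios plasma/CSF, averaged across patients with
sample sd and %CV (100·sd/mean, undefined below two complete pairs — the
two-or-more-patients inclusion rule — or at zero mean). The equal-protein
basis divides each fluid column by its total protein (the equal-load
comparison); multiplying an equal-protein ratio by the total-concentration
ratio recovers the equal-volume ratio (albumin: ~1 × 70/0.4 ≈ 175). Bands on
the equal-protein mean ratio — high > 0.4, low < 0.2, boundaries in mid —
annotate the combined overview; high-band proteins are the ones whose CSF
concentration blood contamination moves most.

## MRM quantification

Peptides are quantified as endogenous/SIS (stable-isotope standard)
peak-area ratios on the most intense transition free of interference (≥ 3
transitions monitored per peptide; all-flagged peptides are excluded and
logged). Peptide ratios roll up to proteins as the median — robust to a
single interfered peptide — with the peptide count recorded. The
quantifiability filter retains proteins with ≥ 2 unique peptides in ≥ 2
contexts (samples/patients) and reports every exclusion with its reason.

## Synthetic-data generator

The generator is first-class, tested code defining the study conditions.
Per origin class, equal-volume ratios r are log-uniform: CNS and
leptomeningeal 0.05–5, liver-derived plasma proteins 50–15 000, mixed-origin
5–50, cellular proteins 0.05–1 in the plasma phase with cellular enrichment
10³–5·10⁴ and cell-associated fraction 0.9–1. Liver-protein CSF levels are
drawn as a plasma level (log-uniform 50–5000) divided by r, reproducing the
real anti-correlation between barrier passage and CSF concentration. An
albumin-like sentinel (accession `SIM-ALB`, r = 177, gradient amplitude
1.58, flagged as depletion-list member) is always present with a CSF
concentration 1.2× the sum of all others, making it the dominant protein by
mass as albumin is in CSF; the resulting total-protein plasma/CSF
concentration ratio comes out near 150∶1, the right order for the ~200∶1
physiological value. Gradient amplitudes: 1 for CNS (flat — the brain-derived
proteins show no gradient), the plasma amplitude (default 1.6) for plasma
and cellular classes, 1.15–1.35 for leptomeningeal and 1.05–1.30 for
mixed-origin proteins. An optional flag adds a one-point cellular boost at
RCG point 1, emulating puncture erythrocytes in the first collected
millilitre.

Technical noise is multiplicative log-normal, mean 1, applied independently
per (protein, sample) with CV = `noise_cv` (default 0.20, σ² = ln(1 + CV²));
expected abundances therefore equal the closed-form forward model exactly,
and the noise-free simulator is bit-identical to it. Patient-to-patient
variability of barrier passage multiplies the plasma column by a per-protein
log-normal factor with ln-sd 0.35 (≈ 36% between-patient ratio CV,
matching albumin-scale variability). Seeds are mandatory; catalogs and
matrices are bit-reproducible given seed and spec.

What the generator does *not* emulate: peptide-level digestion and
flyability, retention-time or spectral structure, interference other than
the MRM flag mechanism, protein degradation by blood proteases, correlated
(batch) noise, and decreasing rostro-caudal gradients (amplitudes are ≥ 1;
flat CNS proteins follow the replicated finding that brain-derived proteins
do not decrease along the column). Passing tests on synthetic data therefore
demonstrate the correctness of the computations and the internal consistency
of the models, not robustness to every artefact of real LC-MS data.

### Noise and classification accuracy

One consequence of per-sample 20% CV worth stating explicitly: a ratio of
two independently noisy abundances has ln-scale sd √2·√ln(1.04) ≈ 0.28, so
for a genuinely flat protein the probability that an observed spike ratio
stays below 1.2 is only ≈ 0.74 per level (≈ 0.62 for both levels jointly,
with the shared-reference correlation). Flat proteins therefore drift into
the *uncertain* band at an appreciable rate — as they visibly do in the real
data, where the uncertain band is populated — while being called *affected*
outright remains rare (≲ 15%). The recovery tests assert what the noise
model supports: ≥ 95% of plasma-class proteins called affected, ≤ 20% of
CNS-class proteins falsely called affected, and exact (100%) label recovery
in the noise-free limit.

## Numerical choices and problem sizes

Duplicate channels are averaged arithmetically on the linear scale before
ratio computation; zero reference abundances yield missing ratios; fewer
than three non-missing gradient points marks a protein not-evaluable and it
is counted, not dropped silently. End-point fold changes use the observed
point ratios (the fitted-line endpoints are available behind a flag).
Symmetric fold change max(r, 1/r) is the classification default so that
decreasing proteins remain detectable, with direction carried separately.

Default test problem sizes — 200–500-protein catalogs, 100 seeded
recovery runs, 1000 random inputs against the least-squares oracle — keep
the whole suite in a few seconds on one CPU while leaving Monte-Carlo
margins of several standard errors on every stochastic assertion.

## Known limitations

Single-patient gradient designs cannot separate patient idiosyncrasy from
the gradient itself (the model's 1.6-fold default is one patient's value;
replication patients showed 1.3–1.45 over 20 mL). The inverse contamination
estimator assumes the catalog's r values apply to the sample's donor, i.e.
an intact barrier; barrier impairment inflates apparent f. Accession-group
alignment fails loudly on leader/member conflicts rather than resolving them
heuristically. The equal-volume 177∶1 albumin anchor is a population-scale
constant, not a per-patient measurement.
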