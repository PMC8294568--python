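# Methods

## Production-rate estimation

Concentrations are carried in mM throughout; "per gram of sample" and
"per mL of slurry" variants of that unit are treated as the same numeric
scale. The rate for one (donor, condition, SCFA) is the two-point slope of
the replicate-averaged concentration over the 2–4 h window — the window in
which fermentations are reliably in their linear regime — not a
least-squares fit over all timepoints (a least-squares option exists behind
a flag). Replicates are averaged before the slope; for a balanced two-point
design the result is identical to averaging slopes afterwards. The control
(no spike-in) slope is subtracted to isolate fiber-attributable production;
negative net rates are retained because the downstream z-scoring assumes
values on the whole real line. Cellulose serves as a negative control: it
is generated (and, in real assays, observed) to be indistinguishable from
the no-spike condition.

Replicate QC reports, per (donor, condition, timepoint, SCFA) group with
two or more wells, the coefficient of variation `100·sd(n−1)/mean`, and as
an alternative reading the range-over-mean percentage difference; the
overall statistic is the unweighted mean of group CVs. Zero-mean groups are
flagged, never silently dropped.

## The MMP matrix and typing

The phenotype matrix has one row per donor and six columns
({inulin, pectin} × {acetate, propionate, butyrate}), z-scored per column
with the sample (n−1) standard deviation; constant columns are flagged and
mapped to zero instead of dividing by zero, and the per-column mean/sd are
stored so the transform is invertible. High/low producer status is the
z-score sign with the boundary inclusive on the high side (z ≥ 0 is high).

Typing uses agglomerative average-linkage (UPGMA) clustering of donor rows
under Euclidean distance (the distance is configurable; Euclidean on
z-scores is the default because all columns are on a common scale after
standardization). The cut is user-chosen — count k (default 2, matching a
two-type reading of the cohort) or height — with no automatic model
selection. scipy's implementation supplies the deterministic
lowest-index-first tie-break. A text Newick export of the dendrogram is
provided; no plotting.

Stability across two visits is a 2×2 contingency table over all
donor × column cells (rows = visit-1 class, columns = visit-2 class,
order high/low) and a two-tailed Fisher exact p-value using the
point-probability rule (sum of probabilities of all margin-fixed tables no
more probable than the observed one) — the most common convention for a
two-tailed Fisher test. The contingency compares binary high/low classes,
equivalent to sign-concordance of the continuous z-scores.

A note on null behavior: exact-test p-values are discrete and
conservative, so under independent visits their distribution is only
approximately uniform — the mean sits slightly above 0.5 and a plain
Kolmogorov–Smirnov test against U(0,1) can reject even when the test is
perfectly calibrated in the frequentist sense. The test suite therefore
checks size control (the fraction of p < 0.05 stays near or below 5%) and
uniformity of the mid-p transform (p minus half the point probability),
which is the standard continuity correction for discrete exact tests.

## Community analysis

Pipeline order is fixed: depth filter → rarefy → normalize → (collapse) →
classify. Samples with strictly fewer than 5,000 reads are dropped
(a sample with exactly 5,000 is kept). Rarefaction subsamples each sample
without replacement to the lowest remaining depth using the multivariate
hypergeometric distribution, deterministically per seed. Diversity uses
the rarefied counts; classification uses total-count-normalized relative
abundances (a flag switches to rarefied input). Taxonomy collapse truncates
7-rank lineage strings at the requested rank and pools features unassigned
at that rank into one `<parent lineage>;unassigned` feature per parent, so
an unassigned-genus OTU of a known family is not merged into that family's
named genera.

Shannon diversity uses the natural logarithm with 0·ln 0 ≡ 0; the
Jensen–Shannon distance is the square root of the divergence with log base
2, so it is bounded by 1. Both conventions are recorded in output metadata
because neither is universal.

The high/low classifier is a random forest (500 trees, √p features per
split) under stratified 5-fold cross-validation, per-fold ROC curves
vertically averaged on a fixed 101-point false-positive-rate grid, with
mean AUC the mean of per-fold AUCs and feature importances (mean decrease
in impurity) averaged over folds. Defaults were chosen for stability at
cohort sizes around n = 40, where per-fold test sets are small and
individual-fold ROCs are coarse. Everything is reproducible given the
seed. No claim is made of reproducing any particular cohort's AUC values:
those depend on the underlying sequencing data and OTU clustering.
Baseline stool-content classifiers use the 0 h concentration z-scored
across donors with the same ≥ 0 rule.

## Absorption model

Single luminal compartment, single SCFA: d[B]/dt = φ − k[B] with constant
production φ (mM/h) and first-order uptake k (1/h), initial concentration
c₀ (default 0) and transit time τ (default 12 h). Closed forms:

- C(t) = φ/k + (c₀ − φ/k)·e^{−kt}; for k·t < 1e−8 a second-order series
  c₀ + φt − kt(c₀ + φt/2) avoids catastrophic cancellation and covers
  k = 0 exactly.
- absorbed(τ) = V·∫₀^τ kC dt = V·(φτ − C(τ) + c₀); excreted = V·C(τ);
  produced = V·φτ. Mass balance produced + V·c₀ = absorbed + excreted is
  exact by construction.
- For c₀ = 0 the absorbed fraction is 1 − (1 − e^{−kτ})/(kτ): strictly
  increasing in kτ, → 0 as kτ → 0, → 1 as kτ → ∞, independent of φ.

The bundled uptake constants are printed in the source literature as
mmol L⁻¹ h⁻¹ cm⁻², which is dimensionally inconsistent with a first-order
term k[B]. The default `identity_rate` mode therefore applies the printed
numeric value directly as k in 1/h — equivalent to folding the
surface-to-volume ratio and unit conversion into the constant — which is
the unique simple reading under which the CaCo-derived constant at a 12 h
transit absorbs ~40% of produced butyrate while the dialysis-bag constant
leaves the large majority excreted. A `surface_scaled` mode exposes
k = γ·S/V·u (defaults V = 2 L, S = 2000 cm², implementation placeholders,
not measured values) for sensitivity analysis. Absolute mmol outputs
additionally require a luminal volume; per-donor comparisons are
volume-independent because absorption is exactly linear in φ.

The two-phase variant models substrate depletion: production runs until
t₁ and stops; afterwards C decays as C(t₁)e^{−k(t−t₁)} while uptake
continues until excretion at τ. It reduces exactly to the single-phase
model when t₁ ≥ τ. This captures the regime where stool SCFA concentration
reflects mostly how long the stool transited after production ceased. An
independent step-halving RK4 integrator of the ODE plus the absorbed
integral serves as a numerical oracle in the tests (agreement to 1e−8
relative); it is not part of the model surface. Out of scope by design:
spatially resolved colon models, pH-dependent uptake, and cross-feeding
kinetics between SCFA pools.

## Synthetic cohort generator

The generator emulates the study-shaped inputs under one root seed with
named substreams (rates, noise, otus, depths, types) so stages can be
regenerated independently. Defaults, and what they emulate:

- **Kinetics.** C(t) = C₀ + (φ_control + φ_fiber)·t at {0, 2, 4} h, two
  replicate wells. Baselines (acetate 15, propionate 5, butyrate 3 mM) and
  control rates (0.8/0.4/0.3 mM/h, 30% relative sd) are typical fecal-slurry
  scales. Cellulose wells use φ_fiber = 0.
- **Phenotype types.** Two whole-profile fiber-preference types: inulin
  responders run at 1.8× the cohort base rates (inulin:acetate 4,
  inulin:propionate 2, inulin:butyrate 1, pectin columns 3/1.6/0.8 mM/h) in
  inulin columns and 0.2× in pectin columns; pectin responders mirror
  that. Per column each donor multiplies the type mean by an independent
  Uniform(0.1, 1.9) factor — wide, bounded heterogeneity: some "low" donors
  produce essentially nothing from a fiber, and there are no extreme
  outliers. Realized type separation is ≈ 2 pooled between-donor sd per
  column. The whole-profile contrast matters: average-linkage clustering
  cannot recover types that differ in only a minority of z-scored columns,
  and unbounded (log-normal/gamma) donor spreads produce straggler donors
  that average linkage splits off as singletons.
- **Replicate noise.** One log-normal factor per replicate well scales that
  well's entire trajectory — modelling replicate scatter as dominated by
  inoculum (slurry) density, which multiplies baseline and production
  together. σ is solved numerically (Gauss–Hermite quadrature + Brent) so
  the *expected replicate pair-CV statistic* equals the target (default
  23.5%); the naive σ = √ln(1+cv²) would undershoot the reported statistic
  because a pair's sample sd underestimates the population sd. Under this
  noise model the within-well kinetic shape is preserved, which is what
  makes slope-based rate recovery accurate at realistic noise levels;
  fully independent per-measurement noise of the same magnitude would bury
  the 2 h→4 h slope and is not how replicate wells of a common slurry
  behave.
- **Visits.** Visit-2 true rates are ρ·visit-1 + (1−ρ)·fresh draw from the
  donor's type (default ρ = 0.9).
- **OTU table.** 60 OTUs, log-normal relative abundances (log-sd 1),
  multinomial counts at Normal(20,000, 5,000) depth (configurable shallow
  fraction at 2,000 reads for filter tests). Producer OTUs are modelled as
  prevalent, low-dispersion core taxa (log-mean 1, log-sd 0.6) shifted by
  2 own-sds in donors whose linked rate is above the cohort mean — the
  mean threshold matches the z ≥ 0 phenotype definition used downstream,
  and the low-dispersion profile is needed for the planted shift to
  survive compositional closure (realized between-class shift ≈ 1.5–2 sd).
  The linkage is an abundance shift, not a full generative regression.

What passing recovery tests shows — and does not. The generator plants
linear kinetics, well-multiplicative noise, compact bounded types and a
single strong producer taxon; recovering them demonstrates the pipeline's
correctness and sensitivity under those conditions, not that real cohorts
cluster this cleanly, that real replicate error is purely multiplicative,
or that real producer associations are this strong. Saturating 24 h
kinetics, pH drift, raw 16S reads and ELISA substrate-depletion curves are
deliberately not simulated.

## Problem sizes in tests

The default suite runs a 40-donor, 2-visit cohort (the study scale) for
recovery tests, a 160-donor cohort (640 independent replicate pairs) for
CV calibration, 200 simulated visit pairs for the null distribution of the
stability test, 1,000 random draws for the mass-conservation property, and
the exhaustive Fisher cross-check over all 2×2 tables with total ≤ 40,
enumerated up to the row/column/transpose symmetry group under which the
two-sided p-value is provably invariant (invariance itself is asserted
separately).

## Known limitations

- The two-point slope uses exactly the 2 h and 4 h points; assays whose
  linear window differs need the window arguments or the least-squares
  flag.
- The identity-rate unit reading of the uptake constants is a documented
  convention forced by the inconsistent printed units; absolute absorbed
  quantities (mmol) are therefore only defined up to the assumed luminal
  volume, and only fractions and between-donor ratios should be compared
  across studies.
- The classifier's small-cohort AUCs have large fold-to-fold variance;
  mean AUC at n ≈ 40 should be read with that in mind.
- Weighted UniFrac and ordination are out of scope (no phylogeny is
  carried); Jensen–Shannon distance is the provided beta-diversity.
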