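# Methods

## The dropout design and what the pipeline estimates

A defined community of 12 strains is assembled either complete or with one
member left out (12 dropout communities). After the community has
stabilized — 96 h of batch culture with a 1:100 dilution into fresh medium
every 24 h — each strain's absolute abundance is measured by strain-specific
qPCR. Comparing strain *y* between the dropout lacking *x* and the full
consortium quantifies the net effect of *x* on *y* in that environment; a
strain whose removal significantly changes many other members is a keystone
of that environment.

## qPCR normalization and detection limits

A qPCR run reports 16S rRNA gene copies per template (5 ng gDNA by default).
Absolute abundance is

    abundance = copies_per_template
                × (gdna_conc [ng/µl] × elution_volume [µl] / template_mass [ng])
                / n_16S / sample_amount [ml or g]

The four factors (strain-specific 16S copy number, gDNA concentration,
elution factor, sample amount) admit exactly one dimensionally consistent
composition yielding copies per ml/g, which is the one implemented. Dividing
by `n_16S` reports genome equivalents (default); a flag reports normalized
16S copies instead.

Detection limits (DTL) are strain-specific and act on the **raw copies
scale**, before normalization. The comparison is inclusive: a readout equal
to the DTL counts as detected. Censored values are stored as 0 with an
authoritative boolean flag rather than as missing, because Bray–Curtis and
medians downstream need numeric entries; classification logic always
consults the flag, never the zero. Strain-specific 16S copy numbers and
DTLs are user inputs in the roster config; the defaults shipped with the
package are synthetic placeholders (documented as such in `types.py`)
suitable only for simulation.

## The r_abs statistic and relationship categories

For focal strain *x*, affected strain *y*, one environment:

    r_abs = median(abs_y in dropout OMM11−x) / median(abs_y in full OMM12)

over replicates (medians by default because all summary plots in this
workflow are median-based; a mean variant is available). Classification is
exhaustive and mutually exclusive, applied in this order:

1. *y* never detected in either community → **below_DTL**;
2. never detected in the full community but detected (strictly more than
   half of replicates) in the dropout → **exclusion**;
3. never detected in the dropout but detected in the full → **positive
   dependency**;
4. otherwise **negative** if r_abs > 1, **positive** if r_abs < 1. A tie
   (r_abs exactly 1) is resolved toward the weaker claim "positive" and
   flagged `neutral` in the record's note.

"Never" (0 replicates) and "detected" (>50% of replicates) are the
operational replicate-level readings of "not detectable" / "only detected";
intermediate detection patterns fall through to the ratio rule. The
significance flag is orthogonal to the category: a two-sided Wilcoxon
rank-sum test compares the replicate groups, with exact enumeration of the
rank-sum distribution whenever both groups have ≤12 tie-free replicates and
the continuity-corrected normal approximation otherwise; two identical
constant groups give p = 1 by convention. BH adjustment is applied within
each (focal strain, environment) family of 11 tests.

**Keystone impact** counts species with raw p < α (default 0.05) *or* a
detection-limit category (exclusion / positive dependency). Raw p is used
for the headline count to match per-panel asterisk conventions; the
Wilcoxon-only and BH-adjusted counts are always reported alongside so the
multiplicity-robust figure is never hidden.

## Community structure

Bray–Curtis dissimilarity, BC(u,v) = 1 − 2Σmin(uᵢ,vᵢ)/Σ(uᵢ+vᵢ), is computed
on untransformed absolute abundances (censored entries contribute 0); a
log10(x + DTL) variant exists behind a flag. PCoA is classical metric
scaling: double-center −D²/2, eigendecompose, order axes by eigenvalue,
keep positive-eigenvalue axes for coordinates while reporting negative
eigenvalues, and fix each axis sign by making its largest-magnitude
coordinate positive (so results are reproducible across runs and BLAS
builds). Both per-sample profiles and median-per-community profiles are
supported; the aggregation level is a config choice.

Group confidence regions are bivariate-normal ellipses from each group's
sample mean and covariance at the chi-square(2 df) 0.95 quantile (5.991); a
sample is an outlier when its squared Mahalanobis distance to *its own*
group exceeds that quantile, evaluated on the first two PCo axes only (the
plane in which the ovals are drawn). A normal quantile rather than a
small-sample t/F correction is used; at the group sizes involved (≥9) the
difference is small, and the Monte-Carlo coverage test pins the behavior.
Singular covariances receive a ridge of 1e-9 × trace with a warning.

One-way PERMANOVA uses the within/between decomposition of squared
dissimilarities (pseudo-F with a−1 and n−a degrees of freedom) and
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), default 9999 permutations.
Samples are put into canonical (sorted-id) order before permuting, and each
comparison derives its own RNG substream from the master seed plus a CRC32
hash of the comparison label, so p-values are independent of evaluation
order. Pairwise comparisons are BH-adjusted. Note that with extreme group
separation p does not reach exactly 1/(1+n_perm): random label permutations
occasionally recreate the original partition and tie F_obs.

## Metabolites, ΔpH, host readouts

Feature tables (samples × features, missing allowed) are filtered by the
strict rule "drop when missing fraction > 0.8". Spent-vs-fresh comparisons
use a two-sided Welch t-test on observed values only — missing intensities
are imputed as 0 exclusively for profile dissimilarity, never for testing.
A feature is *consumed* when significantly lower in spent medium than in
fresh, *produced* when higher, else *unchanged*; tests run on raw
intensities by default with a log mode (invariant to global rescaling)
behind a flag. No multiple-testing correction is applied to the default
per-feature calls (mirroring per-metabolite asterisk conventions); a BH
column is emitted alongside.

ΔpH = pH(spent supernatant) − pH(fresh medium), summarized as the median
per community × environment. Histopathology: four sub-scores (submucosal
edema 0–3, PMN infiltration 0–4, goblet-cell loss 0–3, epithelial damage
0–3) sum to a 0–13 composite mapped to bands 0–3 none / 4–8 mild / 9–13
profound inflammation. The cecal-to-body-weight ratio is a plain quotient.
Host group comparisons reuse the shared Welch test.

## The synthetic-data generator

The generator is ground-truth scaffolding, not an inference claim: no
dynamical model is fitted to any real data anywhere in the package. Within
one 24 h batch it integrates a generalized Lotka–Volterra core

    dxᵢ/dt = xᵢ ( gᵢ(pH)·(μᵢ + Σ_{aᵢⱼ>0} aᵢⱼxⱼ) + Σ_{aᵢⱼ≤0} aᵢⱼxⱼ − Σₚ kₚᵢ xₚ )

with two mechanism plugins:

* **Exclusive-resource acidification** — a single degrader consumes a
  polysaccharide pool, dR/dt = −c·x_deg·R, and
  pH(t) = pH₀ − γ(R₀ − R) − A(t), where A accumulates biomass-linked
  fermentation acid (dA/dt = Σᵢ βᵢ xᵢ max(netᵢ, 0)). Each strain's growth is
  multiplied by a logistic switch gᵢ(pH) = 1/(1+exp(−s(pH−θᵢ))) centered on
  its pH threshold (steepness s = 8 by default; a smooth switch avoids
  integrator discontinuities). The switch gates intrinsic growth *and*
  incoming positive (cross-feeding) terms, since a growth-arrested cell
  cannot exploit either; inhibition acts regardless.
* **Bacteriocin interference** — mass-action killing −kₚᵢxₚxᵢ by a producer
  strain. Zeroing the kill rates is the in-silico analogue of a
  toxin-deletion mutant.

Integration uses LSODA (rtol 1e-8, atol 1e-12) on abundances scaled to
1e9 genome equivalents/ml. At each passage boundary abundances are divided
by the dilution factor (100), resource and acid reset to fresh-medium
state, and populations below 1e-9 scaled units — one cell per ml of
culture, below which a population cannot re-seed the next passage — are set
to exact 0. Step-halving changes endpoints by <1e-6 relative (tested).

The observation model reverses the qPCR normalization: true abundance →
copies per template with lognormal noise (σ = 0.2, a typical well-to-well
qPCR CV), then forward through `normalize_qpcr` with DTL censoring.
Biological replicates differ by lognormal inoculum jitter (σ = 0.05);
technical replicates share a culture and draw independent observation
noise. All randomness flows from one master seed through named substreams
(inoculum, observation, pH, metabolites) so each source can be frozen
independently. Study-design defaults match the emulated experiment:
3 biological × 3 technical replicates (9 wells), 4 passages of 24 h,
1:100 dilution.

### Preset study conditions

The `combined_two_media` preset fixes two media over the same 12-strain
roster. Growth rates (0.35–0.7 h⁻¹) and carrying capacities (0.06–0.5
scaled) span the realistic range for gut anaerobes in rich media, with weak
diffuse competition (~2% effects) among all pairs. In the glucose-like
medium (AF) the producer E.fa kills one target outright and suppresses four
others several-fold; one suppressed target (L.re) is a strong lactic-acid
producer, which makes the producer's dropout *more* acidic than the full
community. In the polysaccharide-like medium (APF) the degrader B.ca has
exclusive access to a 2 g/L resource whose fermentation (γ = 0.5 pH/g/L)
drops the culture ~1 pH unit below the biomass-acid baseline; thresholds of
the four pH-sensitive strains sit between the fully acidified culture
(~pH 5.3) and the degrader-dropout culture (~pH 6.3), so only the
degrader's removal flips their detection. Bacteriocin efficacy is
medium-dependent — active in AF only — mirroring the empirical observation
that leaderless enterocins act in some media and not others; this makes the
producer the top keystone in AF and the degrader in APF, the qualitative
context-dependence pattern the pipeline must recover. A cross-feeder (B.co)
supports two recipients in both media. These numbers were chosen once to
embody the mechanisms at effect sizes the design should detect (≥4-fold
against 20% measurement noise) and are not revisited per run.

### What the generator does and does not emulate

It reproduces the *structure* of the real data — replicate design, serial
dilution, multiplicative measurement noise, strain-specific detection
limits, mechanism-driven exclusions and multi-fold shifts, context-dependent
keystone roles, ΔpH signatures, and a metabolite proxy table (resource
consumption, acid products, producer-dependent amino-acid depletion,
NA-heavy rare features). It does not emulate pipetting/extraction batch
effects, tie-prone discretized readouts, strain evolution during passaging,
spatial structure, or host feedback. Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability of planted
mechanisms under realistic noise — not performance on any particular real
data set.

## Statistical calibration facts worth knowing

With 9 vs 9 replicates the exact two-sided rank-sum test is discrete: its
attainable size at α = 0.05 is 0.0400 (by full enumeration of C(18,9) =
48620 assignments). Two consequences are visible in the validation suite:

* the per-strain false-positive rate under the null generator converges to
  ~4.0%, slightly conservative of the nominal 5%;
* when a dropout scenario plants effects on 3 of 11 strains, the
  probability that the affected-species count is *exactly* 3 is bounded by
  P(no false positive among 8 nulls) = (1−0.0400)⁸ ≈ 0.722 (≈0.89 with the
  BH-adjusted count). The planted strains themselves are recovered
  essentially always (sensitivity ~100% at ≥4-fold effects, σ ≤ 0.2); the
  exact-count ceiling is a property of per-comparison testing at fixed α,
  not of the implementation.

## Problem sizes used in validation

Null calibration runs 1000 simulated null datasets (test suite; 400 in the
acceptance script) of 9+9 wells × 12 strains each; ellipse coverage uses a
single 10000-point Gaussian group; planted-effect recovery uses 200 seeded
datasets; mechanism ablations and the context-dependence check run the full
ODE experiment (13 communities × 3 biological replicates per medium). These
sizes give Monte-Carlo standard errors well inside the asserted bounds
while keeping the default validation run to a few minutes on one CPU.

## Known limitations

* The gLV + plugins model is a caricature of metabolic interactions;
  mechanisms act through two named channels only.
* Exclusion/dependency calls near the detection limit are sensitive to the
  >50% detection rule when a strain's true abundance sits within ~2× of its
  DTL; the preset conditions deliberately keep planted effects clear of
  that boundary, real data need not.
* Wilcoxon on 9 wells from 3 cultures treats technical replicates as
  independent (as the emulated design does); truly culture-level inference
  would aggregate to n = 3 and lose the exact test's resolution
  (minimum two-sided p = 0.1). Both aggregation levels are exposed.
* PERMANOVA assumes exchangeability under the null; with strong dispersion
  differences between groups its p-value conflates location and spread.
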