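# Methods

`amoplsnet` implements the statistical core of a designed untargeted
LC-MS/MS metabolomics study: how much of the chemical variability of a
sample set is attributable to each design factor, which features drive the
factor of interest, and how those features organise chemically. The running
example throughout the package is a grape-berry study — four cultivars
sampled at four ripening dates, skins extracted with two solvents (MeOH,
DCM), ionised in positive and negative mode, with pooled QC injections — but
every routine is written for the general balanced two-factor design.

## Normalization

**PQN.** LC-MS sample preparation introduces multiplicative per-sample
"dilution": every feature of a sample is scaled by a common unknown factor.
Probabilistic quotient normalization estimates that factor as the median,
over features, of the ratio between the sample's intensities and a reference
spectrum, and divides the sample by it. The reference is the feature-wise
median over pooled QC samples (`reference="qc_median"`, default) or over all
samples (`"all_median"`). Two numerical choices matter:

* Zeros are treated as *absent* and excluded from the quotient median.
  Upstream gap-filling encodes missing features as 0; including them would
  drag quotients toward zero.
* The reference is iterated to the fixed point of normalizing the reference
  samples themselves and pinned to median 1. A one-shot QC median is not a
  fixed point of its own normalization, so PQN applied twice would shift
  values a second time by a few tenths of a percent. With the fixed-point
  reference the procedure is exactly idempotent (second-pass quotients are 1
  to machine precision) and exactly invariant to arbitrary positive
  per-sample rescalings — both properties are tested. The iteration
  typically converges in < 20 rounds; it is capped at 500 with a 1e-13
  tolerance.

**Scaling.** After normalization each feature is centered and scaled to unit
sample variance (ddof = 1) so that low- and high-abundance features get the
same leverage in the multivariate model. Zero-variance features are dropped
with a warning. An optional log10(x + offset) transform is available but off
by default; it changes feature weighting, not the model structure.

## ANOVA decomposition and the multiblock model

For the balanced two-factor design with factors A (cultivar) and B (date),
the centered, scaled matrix X decomposes additively and exactly into

    X = X_A + X_B + X_AB + E

where row i of X_A is the mean of X over samples sharing sample i's A-level,
X_AB holds cell means minus both main effects, and E is the within-cell
remainder. In a balanced design the four blocks are mutually orthogonal, so
their squared Frobenius norms partition the total sum of squares; each
block's share is its **relative sum of squares (RSS)**, reported as a
percentage.

The blocks — effects *and* residuals — then feed a consensus-kernel
orthogonal PLS. Each block contributes a kernel K_b = X_b X_b', scaled to
unit Frobenius norm (`block_scaling="frobenius"`) so the residual block,
usually the largest RSS, cannot dominate; the consensus kernel is their sum.
The response Y holds centered dummy columns for the *main* effect levels
only, so the automatic number of predictive components is
(a − 1) + (b − 1) — six for a 4 × 4 design; the interaction participates as
a block but contributes no response columns (`y_effects` overrides this).

* **Predictive scores** are the leading eigenvectors of P_Y K P_Y (P_Y the
  orthogonal projector onto the response space), scaled by the square root
  of their eigenvalue. Being eigenvectors of a symmetric matrix they are
  exactly mutually orthogonal.
* **Orthogonal scores** are the leading eigenvectors of (I − P_Y) K
  (I − P_Y): structured kernel variance unrelated to the design (one
  component by default). They have exactly zero covariance with Y.
* **Saliences** (block contributions): for component t, block b contributes
  w_b t'K_b t; normalised over blocks these sum to 100% per component and
  quantify which effect drives the component.
* **Loadings** are computed against the full scaled matrix, p_c = X't_c /
  (t_c't_c), one value per feature per component, as needed for loading
  plots and marker selection.
* **Sign convention:** each component is flipped so the main-effect level
  with the largest absolute mean score sits on the positive side; ties break
  by level order. This removes the sign indeterminacy of eigenvectors across
  runs and platforms.

A consequence of exact balance worth knowing: because the blocks are exactly
orthogonal, every predictive component is driven entirely by a single block
(saliences are 0 or 100), and residual or interaction variation cannot enter
the Y-space components at all. Mixed block contributions on predictive
components arise only with unbalanced data or augmented blocks. All
structural invariants (salience columns sum to 100, score orthogonality)
hold in either regime. Per-effect "top components" are therefore chosen by
maximal salience with near-ties resolved by the data variance the component
captures, which in the balanced case picks the dominant direction *within*
the effect's subspace.

## Permutation testing

Effect significance uses a permutation test with statistic

    s(e) = Σ_c v_c · salience_{e,c} / Σ_c v_c        (predictive components c)

where v_c = t_c'XX't_c / t_c't_c is the data variance captured along the
component. The weighting is deliberate: after Frobenius normalization the
consensus-kernel eigenvalues are invariant to each effect's amplitude, so
they carry no information about effect size; the data variance along the
score direction does. Null models refit the entire pipeline with permuted
labels — for a main effect the labels are permuted *within the strata of the
other factor* so the factorial stays balanced (a free permutation can empty
design cells, which the exact decomposition cannot handle); for the
interaction the joint cell labels are permuted freely (the label multiset,
and hence balance, is preserved). p = (1 + #{null ≥ observed}) / (1 +
n_perm), 199 permutations by default. Calibration is verified empirically:
over 200 pure-noise datasets the rejection rate at α = 0.05 stays in
[0.02, 0.09] and the null p-values pass a Kolmogorov–Smirnov uniformity
check.

## Marker selection

On the predictive component with maximal salience for the factor of interest
(cultivar), the k most extreme positive and k most extreme negative feature
loadings are selected per dataset (k = 30 by default, the convention of the
motivating study; ties break by feature id). Selections from several
datasets merge with ids deduplicated — a feature extreme in two datasets
counts once among unique markers and appears in `shared_ids` — reproducing
the 2 × 60 → 120 records → 106 unique / 14 shared arithmetic when 14
features are extreme in both datasets. Because a component's sign is
arbitrary, the attractive/unattractive direction is anchored externally: the
component is oriented by the sign of (mean score of attractive cultivars −
mean score of unattractive cultivars) and a marker's direction is the sign
of its loading under that orientation, so a global sign flip changes
nothing. Conflicting directions for one feature across datasets are kept and
flagged, not resolved.

## Molecular networking

Spectral similarity is the modified cosine: square-root intensity transform,
L2 normalization per spectrum, candidate peak pairs within a fragment
tolerance either directly or shifted by the precursor mass difference, and
greedy one-to-one pairing by descending intensity product. The greedy choice
follows common networking practice; a test compares it on random small
spectra against the optimal assignment (Hungarian algorithm) and the
observed divergence is zero at 1e-9. Edges require cosine ≥ 0.7 *and* ≥ 6
matched fragments (both inclusive; tolerances 0.02 Da) by default. Every
feature becomes a node, singletons allowed; connected components are the
chemical clusters, summarised by the number of components with ≥ 3 nodes,
the fraction of features inside them, and which components carry ≥ 3
markers.

Ion-identity edges group features that are different adducts of one
compound: co-elution within an RT tolerance (0.1 min), precursor mass
difference matching an adduct-pair delta ([M+H]+, [M+NH4]+, [M+Na]+,
[M−H2O+H]+ pairs, charge 1), and Pearson correlation ≥ 0.8 of the intensity
profiles over biological samples. The correlation is a stated proxy for
"similar chromatographic peak shape", which exported feature tables no
longer carry; the threshold is configurable. No topology filters (top-K
neighbours, maximum component size) are applied by default.

Nodes are decorated with total intensity over biological samples, per-group
intensity shares (shares sum to 1 per node), and marker status, and the
graph exports to GraphML for Cytoscape.

## Behavioural statistics

Egg counts are standardised to eggs per gram of fruit and log(x + 1)
transformed (natural log; F and p are base-invariant). The overall model is
a fixed-effects ANOVA with sequential sums of squares (statsmodels type-I
`anova_lm` behind the module surface) over box + cultivar + date +
cultivar×date; the design must be balanced, where sequential sums of squares
are order-invariant (verified by permuting term order). When the
cultivar×date interaction is significant at α = 0.05 the pipeline re-analyses
each date with a 2-way ANOVA (box + cultivar), mirroring the branching
workflow of the motivating study. Pairwise cultivar comparisons use
two-sample pooled-variance t tests with Bonferroni adjustment (p × number of
pairs, capped at 1) and an insert-and-absorb compact letter display; the
per-pair variance (rather than the global ANOVA MSE) is the simpler,
conservative choice. Infestation rates are plain percentages reported to one
decimal.

## Synthetic data

The generator produces data under the model the analysis assumes, plus known
ground truth, so every stage can be scored exactly:

* **Feature tables.** log-normal intensities: log intensity = per-feature
  baseline (N(13, 1), arbitrary area units) + planted effect offsets +
  N(0, noise_sd²), multiplied by a per-sample dilution exp(N(0,
  dilution_sd²)). Defaults noise_sd = 0.2, dilution_sd = 0.3 — residual
  spread and dilution ranges typical of well-run untargeted batches. QC rows
  are the feature-wise mean of the undiluted biological intensities with
  noise at noise_sd/4, emulating pooled-material injections. Effects are
  per-level log offsets (centered to sum to zero for identifiability) on a
  subset of features; when a target RSS share is requested the amplitude is
  calibrated from the expected ANOVA sums of squares of the planted linear
  model (including the df·σ² noise leakage into effect estimates and the
  per-feature total-variance normalization that unit-variance scaling
  imposes), solved by a scalar root find inside a fixed-point loop over
  effects. The calibration is exact for the log-scale linear model and
  accurate to a few percent after exponentiation at these noise levels;
  the recovery tests allow ±5 points.
* **Spectra.** Each family has a fragment scaffold; members share a fixed
  core of ≥ 6 scaffold peaks (jittered below the fragment tolerance) with a
  family-wide intensity pattern plus low-intensity private peaks, so member
  pairs exceed the 0.7/6 edge thresholds while decoys — rejection-sampled to
  share < 6 peaks with everything — stay singletons. Adduct variants of a
  compound share RT (± 0.005 min) and differ in precursor m/z by exactly the
  adduct mass difference.
* **Egg counts.** One berry per box × cultivar × date; berry weight ~
  Uniform(1.0, 2.5) g; eggs ~ negative binomial with mean cultivar_mean ×
  weight and shape k = 2 (overdispersed; Poisson is the k → ∞ limit).
* **The full study scenario** (`generate_study`) mirrors the motivating
  design: 4 cultivars (two attractive, two unattractive) × 4 dates × 3
  replicates + 4 QCs, two extract datasets of 300 features, 30 planted
  attractive and 30 unattractive marker features per dataset (cultivar
  offsets ± 0.5 log units), a date effect calibrated to an 18% variance
  share, and spectral families laid over marker features so markers
  aggregate into network clusters. The two extracts get separate feature-id
  namespaces except 14 marker features (7 per direction) detected in both
  under a common id, so the merged marker sets overlap the way two
  extraction solvents of one study do (120 records, 106 unique, 14 shared).

What the generator does *not* emulate: retention-time drift and batch
effects, heteroscedastic or intensity-dependent noise, censoring at the
detection limit, correlated features beyond planted effects and shared
dilution, isotopologues, and chromatographic peak shapes. Passing tests
therefore demonstrate correctness of the algorithms under the stated model,
not robustness to every artefact of real acquisitions.

## Problem sizes and determinism

Simulation-based tests use the study-scale design (48 + 4 samples, 300
features, 199 permutations) where the property concerns the full pipeline,
and reduced designs (12–24 samples, 20–40 features) for the 200-dataset
calibration studies. All randomness flows through `numpy.random.default_rng`
with explicit seeds; identical configuration and seed reproduce every
numeric output byte-for-byte, recorded with checksums in the run manifest.

## Known limitations

* Only balanced, fully crossed two-factor metabolomics designs are
  supported; unbalanced data are rejected rather than approximated.
* The exact-balance salience degeneracy described above means per-component
  block mixing seen in published tables from slightly unbalanced data is not
  reproduced.
* Ion-identity grouping uses intensity correlation, not chromatographic peak
  shape; groupings on real data may differ from tools with raw-data access.
* Annotation (formula/structure/class assignment) is accepted only as a
  pass-through table; the package performs none itself.
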