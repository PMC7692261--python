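# Methods

This note documents the statistical procedures longiprot implements, the
assumptions behind them, the synthetic-cohort generator used for testing,
and the numerical and design choices made where the methodology left room.

## Study design assumed

A two-group longitudinal LFQ plasma study: responders and non-responders
to antidepressant treatment (labels derived from MADRS scores by the
≥50%-reduction-from-baseline rule at the configured evaluation weeks,
default weeks 4 *and* 10, boundary equality counting as response), sampled
at baseline and weeks 1, 4 and 10 (coded as four unordered factor levels
T0 < T1 < T4 < T10, not numeric weeks), each plasma sample measured in two
or three technical replicates, samples prepared in batches that are
balanced across response groups.  A separate, larger cohort provides
paired baseline/week-1 targeted-MS (MRM) light-to-heavy ratios for marker
validation.

## Preprocessing

**Scales.** All modeling runs on log2 intensities.  The NSF normalization
step is defined on the raw scale (its quantities are ratios of raw
abundances), so the pipeline exponentiates back before computing and
applying scaling factors, then returns to log2.  Each stage validates the
scale of its input.

**Batch mean-centering.** Per protein, each batch's mean (over non-missing
log2 cells) is shifted onto the protein's grand mean.  Idempotent;
preserves the per-protein grand mean; missing cells untouched.  Batches
with no observation for a protein are left missing and logged.

**Completeness.** Technical replicates are collapsed to the per-sample
median before completeness assessment and imputation (a sample cell is
missing only when every replicate is missing); replicate-level values are
retained for the mixed model.  Proteins are *complete* (observed in every
sample), *incomplete*, or *excluded* (too few observations to impute:
fewer than k + 2 observed sample cells).

**LLS imputation.** Complete proteins are clustered into k = 15 groups by
average-linkage agglomerative clustering on 1 − Pearson correlation of
their per-sample profiles (deterministic; constant profiles fall back to a
Euclidean nearest-representative assignment, logged).  Each cluster is
represented by its member-mean profile.  Each incomplete protein's
observed cells are regressed (ordinary least squares with intercept) on
the k representative profiles; missing cells are replaced by fitted
values; observed cells are never altered.  Rank-deficient designs fall
back to ridge with penalty 1e-6.  Regressing on cluster representatives
rather than on individual selected proteins is a deliberate choice (the
alternative is ambiguous in the source methodology); representatives
average out protein-level noise.

## Endogenous normalization

**Stability.** Candidate reference proteins (the complete set) are scored
with a model-based two-way gene × sample formulation fitted per response
group, with gene-specific residual variances:

- residuals: `r_igj = y_igj − ȳ_ig· − ȳ_·gj + ȳ_··g`
- `s²_ig = Σ_j r²_igj / (n_g − 1)`; correcting for sample effects
  estimated from a k-gene panel,
  `σ̂²_ig = max((s²_ig − s̄²_g/(k−1)) · k/(k−2), 0)` (derived by
  method-of-moments; the k/(k−2) factor undoes the contraction caused by
  estimating sample effects from the panel itself).
- group bias `d_ig = ȳ_ig· − ȳ_··g`, centred across groups, shrunk towards
  zero with the pooled across-gene bias variance
  `γ̂² = max(mean(d²) − mean(σ̂²/n_g), 0)`:
  `d*_ig = d_ig · γ̂²/(γ̂² + σ̂²_ig/n_g)`.
- stability `ρ_i = mean_g(|d*_ig| + sqrt(σ̂²_ig/n_g))`; lower is more
  stable.  The uncertainty term is the sampling SD of the bias estimate
  rather than its shrunk posterior SD: at the γ̂² = 0 boundary the
  posterior SD vanishes for every gene and the measure would stop ranking
  by intra-group variance.

With a small panel (k ≲ 10) the sample-effect estimates leak a σ̄²/k share
of the other genes' noise into every gene's residuals; stability values
are meaningful for ranking large candidate panels, not tiny ones.

**Selection.** Candidates with a significant group difference are removed
(mixed model without interaction, Wald test of the group coefficient
against a t distribution with n_patients − 2 df — group is a
between-patient contrast and a normal reference is anticonservative at 10
patients), as are proteins on a user-supplied prior-disease-association
exclusion list; the n = 6 most stable survivors are selected, ties broken
by protein id.

**NSF.** `ratio_is = N_is / N̂_i`, `N̂_i` = across-sample median of
normalizer i (geometric mean exposed as an option — the source
formulation is internally inconsistent between the two, and both are
implemented without asserting which was used); `NSF_s` = median over i of
`ratio_is` (same option).  All raw intensities of sample s are divided by
`NSF_s`.  Equivariance (scaling a sample scales its NSF) is exact as long
as the scaling does not move the across-sample reference.

## Longitudinal testing

**Mixed model.** Per protein: fixed effects group (non-responder
reference), time (T0 reference, 3 dummies), group × time (3 dummies) and
replicate index; random intercept per patient; REML for reported estimates
and variance components.  The interaction p-value is a joint
likelihood-ratio test of the three interaction terms from ML fits of the
full and reduced models, referred to χ²₃.  A random time slope and Wald /
replicate-averaged alternatives are deliberately not defaults: four
visits per patient cannot support richer random structures.  Optimization
uses L-BFGS with a retry cascade (default Newton-type, then Powell);
fits that still fail are flagged unconverged and excluded from the
multiple-testing step, with a log entry.  The interaction estimates are
within-patient contrasts and are invariant to patient-level shifts; the
LRT itself moves slightly under such shifts because ML variance
components re-estimate (observed ≲5% relative on strong signals).

Calibration note: the 3-df ML LRT at 10 patients × 8 runs is mildly
anticonservative; on 1000 simulated null proteins the empirical type-I
error at nominal 0.05 is ≈0.06.

**SGoF correction.** With s of n interaction p-values ≤ γ = 0.05, a
mixture posterior decides the metatest: point mass P0 = 0.5 on the
complete null θ = γ against a Beta(a0 = 1, b0 = 1) prior truncated to
θ > γ.  If P(H0 | s) < α = 0.05 the excess over the null expectation,
⌊s − nγ⌋, is declared significant and that many smallest p-values are
flagged; otherwise nothing is.  The classic binomial SGoF is included for
cross-checking.  The excess-over-expectation count (rather than a
sequential decrement to the largest null-compatible count) is the
published metatest's accounting; the sequential variant is severely
conservative at large n for diffuse priors.

**GEE cross-check.** On replicate-merged (median) data, Gaussian GEE with
independence working correlation — the coefficients are therefore exactly
OLS — clustered by patient, with the Wang–Long small-sample covariance:
pooled leverage-corrected residual outer products
`R = mean_i (I − H_ii)⁻¹ e_i e_iᵀ (I − H_ii)⁻ᵀ` (equal cluster sizes
required; the design is balanced by construction), sandwiched as
`(XᵀX)⁻¹ [Σ_i X_iᵀ R X_i] (XᵀX)⁻¹`.  The interaction is tested by a joint
3-df Wald χ² under this covariance.

**Screens.** Uncorrected Mann–Whitney tests per protein and post-baseline
visit, in two contrast families: within-group T0-vs-Tk values, and
between-group per-patient deltas Tk − T0.  Exact null distribution when
the pooled sample is ≤ 20 without ties, otherwise normal approximation
with tie and continuity corrections.  Up/down counts per group and the
three-visit Venn regions are reported.

**MRM validation.** Paired differences on the log2 ratio scale; Wilcoxon
signed rank with zeros dropped (exact for n ≤ 25 without rank ties);
BH adjustment across proteins within each group; a marker validates when
significant in responders (adjusted p < 0.05) and not in non-responders.
Candidate triage intersects three significance sets at week 1: the
within-group T0-vs-T1 screen, the between-group delta screen, and the
SGoF-corrected interaction set.

## Trajectory clustering

Profiles are 6-vectors: group-median (across patients, of per-sample
medians) log2 changes from baseline at T1/T4/T10 for each group.
Invariant to per-protein additive shifts.  Affinity propagation runs on
the Spearman correlation matrix of these profiles (midrank ties), with
preference = median off-diagonal similarity, damping 0.9, a 100-sweep
stable-exemplar convergence window, and a deterministic ~1e-9 jitter to
break exact similarity ties (rank-based profiles produce many; without
tie-breaking the messages settle in degenerate fixed points).  Final
assignment ties break to the lowest item index; exemplars label
themselves.  Affinity propagation is an approximate maximizer of net
similarity: on instances with a unique, well-separated optimum it matches
exhaustive search, but on unstructured random similarity matrices it can
settle in local optima (as does every standard implementation).  The
exact t-SNE embedding (no tree approximation, perplexity 2, PCA
initialisation, seeded) is for visualisation; clustering operates on the
profiles, not the embedding (clustering the 2-D coordinates is exposed as
an option but distorts similarity).

## Clinical correlation

Per-sample protein medians are paired with same-visit scores of six
indices; Spearman's rho (midrank ties) is tested by permutation of the
paired visits — one shared set of B = 10000 permutations (1000 in the
pipeline default, for runtime) across the whole protein × index grid,
p = (1 + #{|ρ_perm| ≥ |ρ_obs|})/(B + 1) — and BH-adjusted over the grid.
Proteins with adjusted p < 0.05 for ≥ 2 indices are reported.  Pooling the
repeated visits treats them as exchangeable under the null; a
patient-stratified permutation would be stricter and is a known
limitation of the pooled default.

## Synthetic cohorts

Per protein, on log2 scale: baseline level μ_j ~ N(20, 2²); patient random
intercept (SD 0.5); per-protein batch shift (SD 0.3); planted archetype
delta surface; a per-sample log-normal loading factor (SD 0.25) shared by
all proteins — the signal the NSF step exists to remove; replicate noise
(SD 0.25).  Six normalizer proteins are abundant (μ + 2), tightly
regulated (noise factor 0.1), batch-free, and carry no group effects.
Defaults are the emulated design's conditions; effect size defaults to a
1.0 log2-unit trajectory amplitude.

**Archetypes.** The six verbal trajectory shapes are realised as
piecewise-linear delta vectors at (T1, T4, T10) in units of the effect
size (see `ARCHETYPE_DELTAS`).  Two constraints shaped the exact values:
"little change" arms carry small non-zero drifts, and archetype 4 has a
non-monotone wiggle, because two strictly monotone surfaces of the same
orientation have identical Spearman rank patterns and no rank-based
similarity could separate them; and adjacent values are spaced ≥ 0.1
effect-size units so that group-median sampling noise does not scramble
the rank patterns at low noise.  Within these constraints the shapes
remain faithful to their descriptions (gradual vs. early-onset group
divergence, early jump then plateau, week-4 dip with week-10 recovery,
near-flat arms).

**Missingness.** Abundance-dependent (MNAR) dropout — per-cell probability
`mcar + (1 − mcar)·logistic((τ − x)/s)` with steepness s = 0.8 log2 units
and MCAR floor 0.002 — applied to non-normalizer proteins.  The threshold
τ is solved at configuration time by nested Gauss–Hermite quadrature over
the generator's own latent model so that the *expected* fraction of
proteins with ≥ 1 missing per-sample cell equals the 0.43 target (a
sample cell is missing only when all its replicates drop, and replicates
share everything but measurement noise).

**Clinical scores.** A latent severity fraction per patient and visit
(responders decline to 0.25–0.48 of baseline by weeks 4–10,
non-responders to 0.55–0.90, with the response rule enforced exactly
after integer rounding); MADRS is the rounded baseline × severity; the
other indices are noisy affine transforms of severity on their instrument
scales (quality-of-life scales load negatively).  Eleven null-archetype
proteins additionally share the standardized severity factor
(link strength 0.8 log2 units), planting the ≥2-index correlations — and,
by construction, genuine group×time signal, since severity trajectories
differ between groups.

**MRM cohort.** 19 responders / 5 non-responders, paired T0/T1 log-normal
ratios (between-patient SD 0.5, paired noise 0.3 log2); planted log2
effects of ±1.5 in responders only (PHOX2B up, SH3BGRL3 and YWHAE down);
five null panel proteins.

**What the generator does not emulate:** peptide-level quantification and
roll-up, correlated protein modules (beyond the planted archetypes),
retention-time or spectral artefacts, batch × time interactions, dropout
at the replicate-acquisition level (missingness is cellwise), and
non-Gaussian heavy-tailed noise.  Passing recovery tests therefore show
the statistical chain is correct under its own assumptions, not that those
assumptions hold for any particular real dataset.

## Problem sizes and determinism

Test and acceptance runs use the design-scale cohort (316 proteins, 80
runs), 1000 null proteins for calibration, B = 199–1000 permutations for
calibration and screening, and low-noise/strong-effect conditions
(effect 2.0, noise 0.05) for exact-recovery checks.  Every random draw
flows from an explicit seed; repeated runs with the same seed produce
byte-identical artifacts.

## Known limitations

- The LMM group main-effect p for normalizer candidacy uses a t reference
  with n_patients − 2 df; Satterthwaite-type df are not implemented.
- The Wang–Long pooling requires equal cluster sizes; proteins with
  missing merged cells are reported unconverged rather than imputed at
  the GEE stage.
- SGoF flags the N smallest p-values; with heavy ties at the declaration
  boundary the flagged set depends on stable sort order (protein input
  order).
- Affinity propagation inherits the algorithm's local-optimum behaviour on
  unstructured similarity matrices.
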