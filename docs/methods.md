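# Methods

This note documents the statistical procedures implemented in `rootcue`,
the assumptions behind the synthetic-data generator, the defaults and why
they were chosen, and the package's known limitations.

## Feature-table curation

A feature table is a features × samples matrix of raw peak areas with
per-feature *m/z* and retention time (RT) and per-sample design factors
(root type ∈ {embryonic, postembryonic}, genotype ∈ {WT, bx1}).

1. **Retention-time exclusion** (`min_rt = 0.3` min). Features eluting in
   the dead volume co-elute excessively and cannot be identified. The
   boundary is resolved as *discard rt < 0.3, keep rt = 0.3*; the
   curation report exposes the removed count so either reading can be
   audited.
2. **Mass-decimal exclusion** (`max_mz_decimal = 0.8`). *m/z* fractional
   parts above 0.8 do not correspond to feasible compounds of biological
   origin in this mass range. The comparison carries a 1e-9 tolerance so
   a value stored as 250.80 is retained despite float representation.
3. **Fragment grouping** (`rt_window = 0.04` min, `r_min = 0.8`). Two
   features are co-elution linked iff |Δrt| ≤ 0.04 **and** Pearson r of
   raw intensities across all samples > 0.8. Groups are connected
   components of this graph (`group_mode="component"`), the chain-wise
   convention of co-elution grouping tools; `group_mode="clique"`
   partitions components greedily into cliques (seeded at the most
   abundant unassigned member) for users who want every within-group pair
   to satisfy both conditions. Correlation uses raw (untransformed)
   intensities because grouping precedes normalization. Zero-variance
   intensity vectors have undefined correlation and receive no edges.
   Tightening either threshold can only split groups, never merge them.
4. **Representative selection.** If a group contains an identified
   compound, its [M−H]⁻ feature is retained; otherwise the member with
   the highest *mean* raw intensity over all samples (mean rather than a
   single-sample maximum, for robustness to one-sample spikes; ties break
   lexicographically on feature id so results are order-invariant). Two
   identified compounds in one group is resolved toward the lower
   [M−H]⁻ *m/z* with a warning; an identified compound without an
   [M−H]⁻ flag falls back to most-abundant with a warning.

## Differential screening

Intensities are transformed with arcsinh(x) = ln(x + √(x²+1)), which is
defined at zero, approximately logarithmic for large values, and
variance-stabilizing for right-skewed positive peak areas. Because
arcsinh is not scale-equivariant near zero, classification is invariant
to a global intensity rescaling only in the large-intensity regime.

Per feature, a two-sided two-sample Student t-test (pooled variance;
`welch=True` gives the unequal-variance alternative) compares the two
root types on the transformed scale. p-values are adjusted by the
Benjamini–Hochberg step-up across features. A feature is called enriched
when its adjusted q < α (= 0.05) **and** its raw-mean fold change
(max/min ratio of untransformed group means, direction attached) exceeds
`fc_cut` (= 2.0). The significance criterion defaults to the adjusted q
(`p_mode="fdr"`); `p_mode="raw"` thresholds the unadjusted p for
sensitivity analysis. Fold changes with a zero mean in one group are
infinite and pass the fold-change criterion when the test is significant;
both-zero features are flagged. Degenerate zero-variance features follow
the convention t = 0, p = 1 for equal means and p = 0 (with a warning)
otherwise.

**Two-way ANOVA.** For the 2 × 2 root-type × genotype design, a fixed-
effects linear model with interaction is fitted per feature on
arcsinh-transformed values. Sums of squares are Type II (each main effect
adjusted for the other; the interaction adjusted for both), the standard
choice for unbalanced observational designs absent pre-specified
contrasts; balanced data reduce to the classical decomposition. The
computation is vectorized: the four model matrices are shared across
features, so each model's residual sum of squares for every feature comes
from one QR factorization (verified against `statsmodels.anova_lm(typ=2)`
to 1e-8 in the tests). p-values are BH-adjusted per term across features.
The **interaction screen** reports (a) features with interaction q < α
after excluding identified compounds (these are examined individually)
and (b) *additional* features with genotype main-effect q < α, i.e. not
already counted in (a) and likewise excluding identified compounds.

## Targeted quantification

Calibration curves are least-squares fits of UV area (265 nm) against
standard concentrations, through the origin by default (a blank has zero
signal), giving the closed-form slope Σxy/Σx². Quantification inverts the
curve and scales by extraction volume over tissue mass to µg g⁻¹ fresh
weight; doubling all areas doubles all concentrations. The MS-to-UV
conversion factor is the through-origin slope of UV against MS areas over
samples where both signals exceed a reliability floor (≥ 3 such pairs are
required); predicted UV values replace measured ones only below the
floor, and every quantified value carries a provenance flag. The floor is
a configuration parameter: the natural default in practice is a multiple
of the blank signal, but no universal threshold exists, so the pipeline
requires it explicitly (`uv_floor`). DIM₂BOA-Glc has no commercial
standard and is quantified on the DIMBOA-Glc curve via the
`curve_fallback` mapping.

Knockout depth is reported as 100 × (1 − Σ mutant / Σ WT) on summed
concentrations — overall, per root type and per compound; the aggregate
number refers to total benzoxazinoids. It lies in (−∞, 100] and equals
100 exactly when the mutant total is zero; a zero wild-type total is
flagged as undefined.

**qPCR.** Per sample, ΔCt = Ct(target) − Ct(reference); ΔΔCt centers ΔCt
on the control-group mean; relative expression is 2^−ΔΔCt. The estimator
is invariant to adding a constant to all Ct values and reproduces powers
of two exactly. Group means and percent knockdown are reported.

## Behavioral statistics

**Preference test.** Within a treatment × timepoint cell the model is an
intercept-only binomial GLM on (count_A, count_B); its closed form is
used: logit = log(a/b), SE = √(1/a + 1/b). Undecided larvae (on neither
option) are excluded from the denominator — the assays report "larvae on
each root type", so absent larvae carry no preference information; an
"off-option as failure" reading would conflate preference with activity.
Overdispersion is estimated as the Pearson χ²/(k−1) over the k dishes;
when it exceeds 1 the Wald SE is inflated by its square root (the
quasi-binomial correction) before the two-sided test of logit = 0.
p-values are BH-adjusted across all cells of an experiment. Cells with
every larva on one option degenerate the Wald statistic and fall back to
an exact binomial test. This per-cell Wald realization stands in for
least-squares-means post hoc contrasts: with an intercept-only cell model
the LSM contrast *is* the cell estimate. The test is label-symmetric
(swapping options negates the logit and preserves p) and its type-I error
at the null sits inside the 99% binomial band around 5% in a
1,000-replicate simulation.

**Damage scores.** Root damage is ordinal 0–5 (no visible damage; 1–3
bite marks; >3 bite marks; bite marks with browning; root partially
removed; root fully removed). The root-type comparison takes per-plant
mean scores per root type and applies a Wilcoxon signed-rank test with
zeros dropped (the convention of the commercial package the procedure is
modeled on). For ≤ 15 nonzero pairs the exact null distribution of W⁺ is
computed by convolution over signed midranks (doubled to integers so ties
are exact); the two-sided p is P(W⁺ ≤ min(w, S−w)) + P(W⁺ ≥ max(w, S−w)),
capped at 1. Larger samples use the tie-corrected normal approximation
with continuity correction. The exact path agrees with a brute-force
enumeration of all 2ⁿ sign patterns for every tested n ≤ 8.

**Treatment comparison.** Kruskal–Wallis with tie correction; all-tied
data short-circuit to H = 0, p = 1. Post hoc, Tukey's HSD is applied to
the joint midranks ("Tukey on ranks" — an approximation of the named
procedure, flagged as such) and summarized as a compact letter display.

**Correlation.** Spearman's ρ via midranks; for n ≤ 9 the p-value is the
exact two-sided permutation probability over all n! orderings, otherwise
the t approximation. Constant margins are flagged rather than tested.

## Cue cross-referencing

Compound names are casefolded, trimmed and passed through an explicit
synonym CSV; there is no fuzzy auto-matching. Unmatched enriched names
within edit distance 2 of an activity entry trigger a warning suggesting
a synonym entry. The candidate list is the intersection of
postembryonic-enriched identified metabolites with the activity table,
hence a subset of both inputs and idempotent.

The packaged activity table (13 compounds) and identified-metabolite list
(28 compounds, 17 root-type differential) are synthetic stand-ins for the
study's supplementary tables, which are not redistributable here: the
four candidate cues, the class labels and the totals come from the main
text (`source_tag = "main-text"`), the remaining rows are plausible
literature compounds tagged `synthetic-placeholder`.

## Synthetic-data generator

The generator exists so that every pipeline stage is testable by
parameter recovery. Each synthetic compound has a latent log-abundance
per sample, mu_c + effects + N(0, noise_sigma²); each fragment observes
it through a fragment-specific yield and small independent log-normal
noise (`fragment_sigma = 0.05`), which guarantees high within-group
correlation by construction; fragments elute within ±0.015 min of the
compound apex, so all pairwise RT differences stay below the 0.04-min
window. Intensities are log-normal — a modeling decision matching
positive, right-skewed peak-area data (the transform then operates in its
log-like regime); the real instrument's noise distribution is not known
to follow it.

Planted effects are multiplicative. Root-type differential compounds get
±½·ln(diff_fold) per root type so the mean ratio equals `diff_fold`;
interaction compounds get a mutant-only root-type shift of
±ln(interaction_fold) (random direction), which produces a pure
interaction with no wild-type footprint — the wild-type screen is
unaffected, and the random sign keeps planted interaction compounds
mutually uncorrelated so co-eluting ones do not merge during grouping;
genotype compounds get ±ln(genotype_fold) in the mutant; benzoxazinoid
compounds are multiplied by `knockout_fraction` (0.03) in the mutant.

Defaults encode the emulated study's printed conditions: 4,956 features;
444 unretained (fraction 444/4956, placed strictly below 0.3 min); 5%
infeasible mass decimals; fragments-per-compound distribution over 1–6
with mean ≈ 2.7 so that ≈ 1,563 informative features remain; 218
root-type differential compounds split 81 postembryonic-up / 137
embryonic-up; 47 interaction and 244 genotype compounds; 10 samples per
design cell (within the study's 7–18 replicate range). Where the study
prints no value the defaults are one-time modeling choices:
`noise_sigma = 0.5` (log-scale biological CV ≈ 50%, typical for plant
metabolite pools and small enough that 4-fold planted effects are
detectable at n = 10), `diff_fold = 4` and folds 8/3 for
interaction/genotype compounds (comfortably above the 2-fold
classification cut so recovery measures the pipeline, not borderline
power).

All generators (features, targeted panel, choice counts, damage scores,
qPCR) draw from independent streams spawned from one integer seed via
`SeedSequence(seed, spawn_key=(stream,))`, so one seed reproduces every
table byte-identically while generators stay independent. Ground truth
(fragment membership, representatives, planted directions, knockout /
interaction / genotype compound sets, identified names) is emitted next
to every table.

The targeted panel uses wild-type concentration means per compound and
root type that follow the reported tissue contrasts (4-fold DIMBOA,
2–3-fold glucosides higher in postembryonic roots, HDMBOA-Glc lower);
mutant concentrations are wild-type draws scaled by 1 − reduction
(default 0.975). Choice counts are binomial (beta-binomial when an
overdispersion parameter ρ > 0 is supplied) after an undecided thinning;
damage scores come from a latent-normal threshold model so a zero effect
gives identical score distributions in both root types; qPCR shifts the
treatment group's ΔCt by −log2(1 − knockdown) cycles (default knockdown
0.75).

**What passing recovery tests shows — and does not.** The generator
reproduces the statistical structure the pipeline assumes (co-eluting
correlated fragments, log-normal noise, multiplicative effects, binomial
counts, ordinal scores). It does not simulate chromatographic peak
shapes, adduct/isotope patterns, ionization suppression, batch drift,
missing values, or insect movement; recovery on synthetic data therefore
validates the implementation and its operating characteristics under the
assumed model, not the upstream peak-picking or the model's fit to any
particular instrument.

## Problem sizes and numerical choices

The test suite exercises the full study scale once (4,956 features, 40
samples; a few seconds) and otherwise uses tables of 200–2,000 features;
simulation-based checks use 300–1,000 replicates, sizes at which binomial
error bands around nominal rates are decisive. Strict inequalities follow
the definitions throughout (r > 0.8, decimals > 0.8 excluded, fold change
> 2, q < 0.05). Correlation edges, BH adjustment and the ANOVA are exact
linear-algebra computations with no iterative fitting; the only
convergence-dependent cross-check (against IRLS-fitted GLMs) is held to
1e-6.

## Known limitations

- Grouping quality degrades when distinct compounds co-elute within the
  RT window *and* correlate above the threshold across samples (e.g. two
  strongly co-regulated metabolites); chain-wise components then merge
  them into one group. The clique mode reduces, but cannot eliminate,
  such merges.
- The Tukey-on-ranks post hoc and the per-cell Wald preference test are
  documented approximations of the named procedures, not re-derivations
  of them.
- The ANOVA screen is restricted to complete 2 × 2 designs with ≥ 2
  replicates per cell; mixed models, batch correction and missing-value
  imputation are out of scope.
- The packaged activity/identified fixtures are partial transcriptions
  with synthetic placeholders; candidate-cue results on real data require
  the user's own curated tables.
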