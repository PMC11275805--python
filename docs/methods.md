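# Methods

## Selection model and score scale

The pipeline models a pooled growth selection: a library of protein
variants competes in culture, and each variant's relative abundance is
read out by sequencing at T timepoints in R replicates. Wild-type
cells double g times between consecutive timepoints (g = 2 by
experimental design, enforced by equipotent dosing in every condition,
drug or control), and a variant with fitness effect s grows 2^(g+s)-fold
per interval. On the log2 scale, after centering each sample on the
synonymous (wild-type-equivalent) variants, a variant's trajectory is
linear in the time index with slope s — so ordinary least squares per
replicate, averaged over replicates, recovers the effect directly in
units of log2 doublings per interval. The time index convention
(0..T−1 vs 1..T) is immaterial because slopes are shift-invariant; the
per-sample sequencing depth is immaterial because the normalization is
per sample.

Normalization uses the **mean** of synonymous log2 counts (the median
is available by passing a precomputed reference, but the mean makes
the synonymous centering identity exact). A pseudocount δ = 0.5 guards
log2(0) on real integer counts; noise-free expected counts are
strictly positive, so exact-recovery checks and the acceptance script
use δ = 0.

## Uncertainty

β is always the mean of per-replicate OLS slopes. Two standard-error
estimators are provided:

* `poisson` (default): sequencing counts are treated as Poisson-like,
  var(log2 c) ≈ 1/((c+δ)·ln²2) by the delta method, with the shared
  variance of the synonymous-mean normalizer added (and its covariance
  removed for synonymous variants themselves), propagated through the
  OLS weights and averaged over replicates. Degrees of freedom are
  effectively large, so tail probabilities are normal. Against
  multinomial simulation this is calibrated: ~95–96% of true effects
  fall inside β ± 1.96·se at depth 10⁶.
* `replicate`: sd of the R replicate slopes / √R with Student-t(R−1)
  tails. This is the honest estimator when replicates carry real
  biological variability beyond sampling noise, but with R = 3 a
  ±1.96·se interval has nominal coverage P(|t₂| ≤ 1.96) ≈ 0.81 — a
  fixed 1.96 multiplier and a 3-replicate t statistic cannot both hold.
  We therefore default to the count-based estimator (the same choice
  count-based enrichment scorers make) and keep this one as an option.

The original analysis this package re-implements used a Bayesian
hierarchical scorer; our deterministic estimator reproduces its score
scale exactly on noise-free data and approximates its uncertainty
semantics: the published "one-sided test of β < 0.5 at cutoff 0.1" is
realized as `tail_prob_resist = P(β < 0.5 | estimate) ≤ 0.1`. Whether
the original cutoff is a local false-sign-rate is unresolvable from
the text; this frequentist surrogate is the declared stand-in.

## Filtering

A variant enters scoring iff (all thresholds inclusive): mean count
over all R·T cells ≥ 4; fraction of zero cells ≤ 10/12; fraction of
zero cells among the R pre-selection (T0) cells ≤ 2/3. Filtering is
per condition; cross-condition operations use the intersection of
survivors and record NA elsewhere. The filter is idempotent and
monotone in each threshold.

## Classification

* Resistance mutation (per inhibitor): `tail_prob_resist ≤ 0.1` AND
  `β_DMSO ≤ 0`. Synonymous variants are excluded by definition (they
  are the reference). Missing DMSO scores yield NA calls.
* Resistance position: ≥ 1 resistance mutation at that position.
* Differential GOF/LOF on γ = β_inh − β_DMSO: GOF iff γ > 0.75, LOF
  iff γ < 0. The 0.75 threshold is exposed as a parameter.
* Within-condition GOF/LOF (distribution-shape sense): two-sided test
  of β against 0, Benjamini–Hochberg corrected across variants at
  α = 0.05. The source text says only "statistically significant";
  BH at 0.05 is this package's declared choice.
* Hotspots: resistance (mutation, inhibitor) pairs are summed per
  position across all inhibitors of a major type (subtypes I_a/I_b
  collapse to I). Summation is per (mutation, inhibitor) pair — a
  mutation resistant to two inhibitors of a type counts twice — which
  is the reading of "sum of counts across all inhibitors".
* Divergent pairs: GOF under inhibitor a (γ_a > 0.75 and, by default,
  a resistance call under a — the "statistically filtered" reading)
  and LOF under b (γ_b < 0); `require_resistance=False` gives the
  laxer γ-only mode.

## Synthetic data: the stated world

The generator emulates the features of the real screen the analysis
relies on, with these defaults:

* Library: 19 missense + 1 synonymous variant per position over a
  contiguous region, plus a nonsense control every 11th position
  (phase anchored at the region start; the real library's stop spacing
  is "evenly spaced" with unstated phase). The real library's exact
  composition (5,764 variants with synthesis fills) is configuration,
  not hard-coded.
* Control (DMSO) fitness: bimodal mixture — neutral N(0, 0.15²) with
  weight 0.6, deleterious N(−2, 0.4²) with weight 0.4; nonsense forced
  below the deleterious mean. The published control distribution is
  described qualitatively as bimodal; these moments are this package's
  choice of a realistic shape and are configurable.
* Inhibitor conditions: neutral variants shift by −1.5 (growth at
  wild-type rate minus inhibition); deleterious variants keep their
  control score; planted resistance (position, mutation) pairs of the
  matching type draw U(0.75, 1.5) under that type's inhibitors and
  −(0.05 + |N(0, 0.1)|) in control. The 0.05 margin keeps the planted
  control score *detectably* ≤ 0 — without it a draw can sit within
  sequencing noise of 0 and the resistance caller's DMSO gate becomes
  a coin flip for a variant that is nominally a planted positive.
  Pairs that collide with the wild-type residue are synonymous and
  stay at 0 (warned).
* Sampling: expected frequency ∝ f₀·2^((g+s)t); each (replicate,
  timepoint) is an independent multinomial of size `depth` (or the
  real-valued expectation with `noise_mode="none"`). No PCR jackpots,
  no overdispersion, no read-level errors — so a green recovery test
  establishes correctness of the estimator under the sampling model,
  not robustness to library-prep artifacts.
* Features: 14-name catalog per (variant, inhibitor). `llr` is the
  control true score plus N(0, 0.5) noise (positively informative);
  `ddG` is −0.8 × control score plus noise (negatively informative);
  `delta_volume` is the real residue-volume difference (Zamyatnin
  volumes); position-level features (`residue_atp_distance`,
  `crystal_rmsf`) are constant across mutations at a position;
  `inhibitor_mw` is constant per inhibitor; the rest are uninformative
  noise with plausible scales. These tables stand in for language-model,
  stability-prediction, docking and pocket pipelines — the predictor's
  tests therefore verify the machinery (splits, constraints, selection),
  not the published feature effect sizes.

All randomness flows from `numpy.random.default_rng` seeded explicitly;
per-condition streams are derived via CRC32 of the condition name so
outputs are byte-identical across runs and independent of hash
randomization.

## Predictor

scikit-learn's `HistGradientBoostingRegressor` with per-feature
`monotonic_cst` (llr +1, ddG −1) replaces the original XGBoost model
(not available in this environment); a seeded random search over
{max_depth 2–4, max_iter 20–150, learning rate 10^U(−1.7,−0.4),
min_samples_leaf 5–50, L2 10^U(−3,1), max_features 0.6–1.0,
max_leaf_nodes {7,15,31}} replaces Bayesian optimization — the original
knobs (booster variant, gamma, alpha, colsample_bytree, grow_policy)
map onto tree-growth limits, L2 regularization and column subsampling.
Ranges are sized for desk-scale tables; the search minimizes MSE on a
20% tuning holdout of the training rows, per feature subset.

Non-monotone features are binned before search: breakpoints default to
training quantiles (4 bins), manual breakpoints are supported for
fidelity to hand-chosen bins, and each value becomes the median of the
training values in its bin (empty bins merge into the nearest filled
bin). Split design: all rows of one held-out type I and one type II
inhibitor, all rows at a random 20% of positions, and all rows of two
random mutant amino acids go to test; the control condition (and any
sole representative of a type) is excluded outright to prevent
type-memorization. Cross-validation partitions positions into k
disjoint groups and amino acids into k groups (re-sampling a few
residues when the count is not k·groupsize, e.g. 18 residues → 10
groups of 2), validating each fold on unseen positions *or* unseen
residues. Subset ranking is by mean CV Pearson r; the winner is refit
on the full training set and reported per inhibitor on test.

Subset enumeration is in binary-counting order over the optional
feature list, so a `subset_cap` prefix is deterministic and spans all
combinations of the first ⌈log2 cap⌉ features. The full 8192-model
enumeration is available by leaving the cap unset.

## Numerical choices and degenerate inputs

* Zero standard error (noise-free data under the replicate method)
  collapses tail probabilities to indicators (0/1, 0.5 at the
  threshold).
* Correlation matrices use pairwise-complete observations; pairs with
  < 3 shared variants get NA with a warning; the diagonal is forced to
  exactly 1.
* `read_counts` treats a missing (variant, replicate, timepoint) cell
  as an error, never an implicit zero; duplicates and negative counts
  are reported with their 1-based file row.
* Pipeline TSVs are written with 6 significant digits and fixed column
  order; the manifest stores sha256 checksums, and a rerun with the
  same config is byte-identical.

## Known limitations

* The scorer is deterministic; it does not reproduce the partial
  pooling of the original Bayesian model, so very-low-count variants
  get wider (Poisson) rather than shrunken estimates.
* The `poisson` standard error ignores between-replicate biological
  variability; on real data with replicate effects, `replicate` (or an
  external scorer) is the safer uncertainty, at the cost of small df.
* The generator's inhibitor shift is uniform across the neutral
  component; real screens show position-structured sensitivity, so
  positional patterns in synthetic heatmaps are not biologically
  meaningful.
* Published dataset-level numbers (specific condition correlations,
  divergent-mutation counts, predictor test correlations) depend on
  the real sequencing data and external feature pipelines and are out
  of scope here by design.
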