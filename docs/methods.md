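# Methods

## Scope and data model

`microsocial` analyses full combinatorial growth experiments: every non-empty
subset (*consortium*) of an N-strain panel grown in replicate wells, with OD
(595 nm) read on a fixed time grid (hourly by default). The unit of
observation is the consortium × condition cell; replicate wells are treated
as exchangeable. Inputs are plain CSV (layout: `well,strains,condition,
replicate` with "+"-separated strain lists; OD: wide `time_h` + well columns,
or long `well,time_h,od`), an optional per-consortium function table, and an
optional rooted newick tree whose tips are the strain IDs.

## Growth-curve features

1. **Baseline correction.** Each well's blank is the minimum of its first
   three readings; corrected OD = raw − blank + ε with floor ε = 0.01 OD
   (values are clipped at ε so logarithms stay defined). This assumes initial
   cell density is small relative to the medium blank, which holds for the
   inoculation volumes the assay uses.
2. **Log-phase detection.** Pointwise slopes of log2(corrected OD) are
   estimated by least squares in a centered window of `slope_points = 7`
   readings (3 reproduces the classic centered difference; 7 suppresses the
   slope noise that proportional reader error injects at a 1 h cadence —
   with 5% multiplicative noise, 3-point slopes have sd ≈ 0.05 gen/h, the
   same order as typical rates, and the detected window collapses to a few
   points). The log phase is the maximal contiguous run of slopes ≥
   θ·max-slope containing the max-slope point, θ = 0.5 by default. Wells
   whose corrected OD never rises 0.02 above the floor, or whose maximum
   slope is non-positive, are reported as `no-growth` with n = k = 0 (a
   status flag, not an error).
3. **Fitness.** n = (log b − log B)/log 2 with B, b the corrected ODs at the
   window ends; k = least-squares slope of log2(corrected OD) over the window
   (generations/hour). On an exact exponential the window is the full span
   and both are recovered exactly; n = k·(window length) then holds to
   numerical precision. Negative n (a declining interval) is preserved and
   flagged; it is clipped to zero only as a ranking key.

**Known bias.** On saturating (logistic) curves the θ = 0.5 window runs from
the start of growth to roughly the biomass inflection, so the window-averaged
k underestimates the low-density rate by ~15–20%. This cancels in all
relative analyses (ratios of k across consortia), which is why the package's
quantities are interval-based rather than parametric fits. Users wanting the
asymptotic rate can raise θ or fit a parametric model outside this package.

**Aggregation.** Replicates are combined by arithmetic mean (sd retained for
the stability analysis); a no-growth replicate contributes its zero to the
mean and flags the row. A consortium × condition cell with no usable wells is
excluded downstream with a warning.

## Social classification

For focal strain i, condition and metric (n or k) fixed: w_c = (consortium
mean fitness) / (focal monoculture mean fitness) for every consortium c. The
partition is w_p (c containing i; 2^(N−1) sets, the focal monoculture
contributing exactly 1) versus w_np (2^(N−1) − 1 sets). The default uses the
complete design; `exclude_monocultures` restricts to mixed communities.
Monoculture fitness ≤ 1e-6 is refused as a denominator rather than producing
unstable ratios.

Decision rule, in order: (1) both groups constant up to float round-off →
neutral, p = 1, flagged degenerate; (2) **negative** if all of w̄_a, w̄_np,
w̄_p are strictly > 1, or the two-sided Welch t-test of w_p vs w_np has
p < α (default 0.05) with w̄_p < w̄_np; (3) **positive** if p < α with
w̄_p > w̄_np; (4) **neutral** otherwise. The all-means clause deliberately
overrides a significant positive difference: a strain that is relatively
fitter in every data set than alone is a net beneficiary of others. Welch
(unequal variances) is used because group sizes and spreads differ; the test
is two-sided. Overall per-strain labels across conditions/metrics take any
negative call as negative, else any positive as positive, else neutral —
the conservative union a practitioner applies when choosing an inoculum.

The all-means clause is informative only when community fitness genuinely
differs from monoculture fitness. In a perfectly symmetric null (all means
exactly 1 in expectation) the strict `> 1` comparison is decided by the focal
monoculture's replicate noise and fires on about half of the calls; the
calibration studies therefore quantify the t-test part (its type-I rate is
nominal), and the synthetic study panel is built so that the clause is inert
for true neutrals (see below).

## Diversity and stability

Richness groups contain all C(N, r) consortia of richness r; values are
normalized by the single fittest monoculture of the same metric (ties broken
lexicographically), so 1.0 marks the best individual strain. The cumulative
analysis ranks strains by monoculture fitness (descending, lexicographic
tie-break) and, for each m, collects all 2^m − 1 subsets of the top m;
consortia with normalized fitness > 1 are tabulated. Normalization is
scale-invariant by construction.

The stability index is CV = sd/mean over replicates (sample sd, n−1
denominator, the standard diversity–stability usage); consortia with
non-positive mean are excluded with a warning. CV (and, when provided,
function) is regressed on richness by OLS both on per-richness medians (the
primary read-out) and on all per-consortium points; both slopes and r² are
reported because the two conventions differ and neither is canonical.

## Phylogeny versus fitness

Communities are presence/absence tip sets, so the distance is **unweighted
UniFrac**: branch length leading exclusively to tips of one community over
branch length leading to tips of either, computed from cached per-edge tip
sets. Input trees with a basal polytomy are used as rooted at that basal node
(logged notice) — the convention classic UniFrac tooling applies to unrooted
trees; branch lengths must be non-negative with positive total.

The association test is a one-term PERMANOVA (**adonis**): G = Gower-centered
−D²/2, SS_model = x'Gx/x'x for the centered covariate x, pseudo-F =
SS_model/(SS_resid/(n−2)), R² = SS_model/SS_total, and p = (1 + #{F_perm ≥
F_obs})/(1 + n_perm) over seeded covariate permutations (999 by default;
`n_perm="all"` enumerates exactly for small n). R², F are invariant to affine
transforms of the covariate and to consistent relabeling. A degenerate zero
residual (distances an exact function of the covariate) yields F = ∞ rather
than an error. One (condition, metric) fitness slice is tested per run; an
auxiliary regression of per-consortium maximum patristic distance on fitness
covers the "maximum phylogeny distance" reading of the same question.

## Function analyses

Consortia are grouped by their members' overall labels: all
positive/neutral, all negative, mixed (excluded), unlabeled (excluded). The
group comparison is a two-sided Wilcoxon rank-sum on per-consortium function
values (the claim is about medians; a Welch t-test is available via
`group_test`), reported with group medians and their fold change.
Fitness–function association is reported as both Pearson and Spearman
coefficients with p values, requiring ≥ 3 matched consortia.

Ranking: mean n descending (negative means clipped to 0 for the key only),
then mean log-phase time ascending, then canonical ID — a deterministic total
order.

## Synthetic experiments

The generator realizes the positive/neutral/negative taxonomy with the
minimal additive model: strain i has intrinsic rate r_i (gen/h), yield K_i
(OD), and community effects δ_i (rate) and γ_i (yield) applied in mixed
communities only. A consortium grows logistically with rate mean(r_i) + Σδ_i
(floored at 0.01 gen/h) and yield mean(K_i) + Σγ_i (floored at initial OD +
0.05). Readings are blank (0.05 OD) + cells(t)·exp(N(0, σ)): log-normal,
proportional-to-signal noise, σ = 0.05 by default; the blank is noise-free so
reader error scales with biomass as in practice. Initial cell OD defaults to
0.01 — equal to the baseline floor, so on clean data the correction step
recovers the cell curve exactly. Seeds are mandatory; identical
configurations produce byte-identical CSVs.

The default **study panel** mirrors the motivating seven-strain panel's
taxonomy: one net-positive strain (δ = +0.06 = 0.3·mean rate, γ = +0.10),
two neutral, four net-negative (δ = −0.06, γ = −0.10), with mild (±10%)
intrinsic heterogeneity. The net-negative majority keeps mixed-community
fitness below monoculture fitness, which makes the all-means>1 clause inert
for true neutrals — the regime in which the published decision table is
meaningful. A symmetric design (one positive, one negative, rest neutral)
instead centers every mean at exactly 1 and turns the strict all-means clause
into a coin flip on replicate noise; it is retained only as a degenerate
case, not as a default. The **null panel** (identical strains, zero effects)
calibrates the t-test part of the classifier.

Calibration and recovery studies (tests and `scripts/acceptance.py`) use 200
seeded experiments per study at one condition, triplicate, 5% noise, the
design size the statistics stabilize at while the whole study stays around a
minute of CPU. Classification per environment is the per-study unit; joining
across environments is the separate pessimistic union rule.

The synthetic function is value = a + b·n_true + bonus·[all members have
non-negative effects] + N(0, σ_f), defaults a = 2, b = 5, bonus = 12,
σ_f = 3 — chosen to put the two social groups' median function roughly
1.5–1.8-fold apart, the contrast magnitude the assay is meant to detect.

**What the generator does not emulate:** pairwise (who-with-whom)
interactions — effects are per-strain and additive, matching what a net
presence/absence comparison can measure; resource competition dynamics; lag
phases; plate position effects; condition-specific strain physiology
(conditions are statistical replicates of the same parameters). Passing
recovery tests therefore demonstrates correctness of the inference given the
net-effects model, not robustness to mechanistically structured real
communities.

## Numerical conventions

Floats in all outputs are written at 6 significant digits; rows are
deterministically ordered (canonical consortium IDs: members sorted, joined
with "-", or "+" if any member contains a dash). Re-running any pipeline with
identical inputs and seed reproduces byte-identical outputs. Permutation
p values have resolution 1/(n_perm + 1) and can never be 0. All randomness
flows through explicit seeds (`numpy.random.default_rng`).

## Limitations

- The social call is a *net* effect; it cannot attribute mechanism or
  identify pairwise antagonists.
- The all-means>1 clause uses strict sample-mean comparisons, as published;
  with means hovering at 1 it is noise-driven (see above). Interpret negative
  calls that rest on it alone together with the reported means.
- Replicate counts in the motivating design (triplicate) give the t-test
  limited power for small effects; the recovery guarantees quoted in the
  tests hold at |δ| = 0.3·mean rate and 5% noise.
- UniFrac here is unweighted (membership only) by design — the experiment
  does not measure within-consortium abundances.
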