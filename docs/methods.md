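# Methods

## Model and procedure

The package targets the matched two-class design: each patient *i*
contributes one normal-tissue value *X<sub>ij</sub>* and one tumour value
*Y<sub>ij</sub>* per feature *j*. The working model is additive on a latent
log scale,

    Y_ij = mu_j + theta_j + alpha_i + eps_ij
    X_ij = mu_j           + alpha_i + eps_ij

with a per-feature baseline mu_j, a per-patient effect alpha_i shared by
both halves of a pair (the "stable confounders" — overall RNA yield,
hybridization efficiency, constitution of the patient), independent
residuals eps, and a disease effect theta_j that is zero for null features.
Because alpha_i enters both halves identically, it cancels in the paired
difference; this is the entire statistical case for pairing, and the
simulator's `test_patient_effects_cancel_in_paired_differences` property
checks it directly.

The selection pipeline is: cross-normalization → modified Wilcoxon test
with misclassification accounting → bootstrap filter → fold-change filter.

### Cross-normalization

Each class is divided by the opposite class's per-feature arithmetic mean
(tumour by X̄_j, normal by Ȳ_j). Among the algebraic variants that
"rescale by the opposite class", division was adopted because it works on
non-log intensities as ratios, treats the classes symmetrically, is
invariant under a common rescaling of all intensities, and demonstrably
widens the gap for a true effect (tumour ratios > 1 inflated, normal
ratios < 1 deflated). The transform is pluggable (`strategy="divide"` /
`"subtract"`); the subtractive variant is provided for comparison but is
not scale-invariant and is not the default.

A consequence worth knowing: after CN the *sign* of a pair's difference is
sign(Y_ij·Ȳ_j − X_ij·X̄_j), so all N signs of one feature share the random
ratio Ȳ_j/X̄_j. Signs of CN differences are therefore **not** independent
under the null — a chance excursion of the class-mean ratio can flip all
N signs coherently. See "Known limitations".

### Modified Wilcoxon test

Standard signed-rank machinery on the CN differences: zeros dropped,
average ranks for ties, smaller rank sum R converted to
Z = (R − n(n+1)/4)/sqrt(n(n+1)(2n+1)/24), two-sided p = 2Φ(Z). Sidedness
is two-sided throughout (conservative; matches the magnitude of typical
reported values). Three small-sample correction policies are available:

* `continuity` (default): recompute Z from R + 0.5. The usual correction
  for approximating a discrete statistic by a continuous law.
* `none`: raw normal approximation.
* `shrink:c`: multiply Z by sqrt((n−c)/n) — a variance-inflation-style
  factor for users who want a more conservative tail.

No single correction is privileged by external evidence, so the policy is
recorded with the results and is a config/CLI flag. The normal
approximation is adequate from n = 6 (within 0.01 of the exact
permutation tail at complete separation) and is the only p-value offered —
exact enumeration for large N is out of scope, matching field practice for
screens at this scale.

Per feature the sign table (t⁺, t⁻, zeros) is tabulated;
misclassification count = min(t⁺, t⁻); a feature is CDS iff all N pairs
carry the same strict sign (any zero difference breaks CDS — a tie
separates nothing). CDS/misclassification are judged on CN differences,
consistent with the pipeline order.

### Sign-symmetry test

P(≤ s minority signs in N fair-coin pairs), one-sided lower tail,
Bonferroni-multiplied by the number of features screened (default: the
number of features in the matrix; 22,283 for the U133A array). The
one-sided tail is the form that reproduces the canonical worked example
(s = 2, N = 27, M = 22,283 → 0.062); a two-sided option doubles the tail.
The adjusted value annotates results; it is a plausibility bound, not a
selection filter.

### Bootstrap filter

Resampling unit: **patient pairs**, with replacement — the pair is the
exchangeable unit of a matched design, and resampling it preserves the
within-pair dependence that is the premise of the whole analysis. CN is
recomputed inside every replicate (class means move under resampling).
Bootstrap P = #(P_boot < P_test)/n_boot with a strict inequality; default
n_boot = 9,999. Replicates that draw fewer than two distinct patients are
redrawn. A `signflip` null (random exchange of class roles within pairs)
is available for users who want a classical permutation-style reference.

Because p depends only on (R, n) and a zero-error feature already sits at
the minimal attainable p for its N, tie-free complete separators have
Bootstrap P exactly 0; the filter bites on fragile separations and on
features whose observed p is not extremal (e.g. features with zero
differences, whose effective n can grow in a replicate).

### Selection regimes

* **strict**: 0 misclassifications, MWT p ≤ 0.05, Bootstrap P < 0.05,
  fold change > 1.35.
* **relaxed**: ≤ 2 misclassifications (configurable), MWT p ≤ 0.05,
  Bootstrap P < 0.01, fold change > 1.2 — a lower fold floor paid for with
  a tighter bootstrap cut.

`ECDConfig` carries both threshold sets explicitly and `run_ecd` evaluates
both regimes in one pass; the bootstrap (the expensive stage) runs once
over the union of candidates (within the relaxed error budget and past the
MWT alpha), so the result table always carries both `selected_strict` and
`selected_relaxed`. Filters are applied in pipeline order but the final
sets are order-independent conjunctions; each stage logs how many features
it removed.

### Baselines and overlap

Paired t-test (t = D̄√N/sd(D), N−1 df; zero-variance rows degenerate to
p = 0 or 1) and the standard Wilcoxon signed-rank test (same machinery as
MWT, raw differences, continuity correction) consume raw intensities and
are unaffected by CN. BH-FDR adjustment is delegated to statsmodels;
ranking for cross-method top-k comparisons uses the adjusted p with
feature-id tie-breaks for determinism. Overlap significance of two lists
in a universe of size 13,074 (non-redundant RefSeq genes on U133A) is the
upper-tail hypergeometric; a two-sided mode uses Fisher's exact test on
the corresponding 2×2 table, since published enrichment values mix the
two conventions.

## Synthetic data

The generator draws the random-effects model above on a latent log2 scale
and exponentiates (base 2) into positive, MAS5-like intensities. Defaults,
chosen once as a realistic 27-patient screen:

| parameter | default | meaning |
|---|---|---|
| n_patients | 27 | matched pairs |
| n_features | 10,000 | screen size |
| effect_fraction | 0.01 | fraction of features with theta ≠ 0 |
| theta_mean / theta_sd | 2.0 / 0.5 | disease effect, log2 units (4-fold average), random sign |
| alpha_sd | 1.0 | patient effect, log2 units |
| eps_sd | 0.5 | residual noise, log2 units (~40% CV) |
| mu_mean / mu_sd | 9.0 / 1.5 | baseline ≈ 2^9 = 512 intensity units |

`intensity_transform=False` gives a linear-scale mode (latent values
shifted positive) used for closed-form checks such as theta recovery from
mean paired differences. Each model component draws from its own child
stream spawned from the seed, so realized baselines do not change when,
say, the number of spiked features changes.

What the simulator emulates: positive paired intensities, strong
within-pair correlation, multiplicative disease effects. What it does not:
probe-level Affymetrix noise, batch effects, inter-gene correlation,
heavy-tailed outliers beyond log-normality. Passing tests on this
generator show the pipeline's statistical behaviour under its own model
assumptions, not performance on real arrays.

## Numerical choices and degenerate inputs

* Intensities are used non-log; zero/negative cells are floored at a
  configurable epsilon (default 0.01 intensity units) with a warning, so
  CN's divisions stay finite without discarding features.
* Ties in |d| get average ranks; exact zeros are dropped before ranking.
* All-zero-difference features: p = 1, no Z, flagged degenerate, never
  selected.
* Result tables sort by (p ascending, |Z| descending, feature_id
  ascending) — fully deterministic; numeric output at 6 significant
  digits round-trips through TSV.
* All randomness (simulation, bootstrap) flows from explicit integer
  seeds; the bootstrap refuses to run without one.
* Test-suite problem sizes: bootstrap at n_boot = 999 and simulations at
  ≤ 10,000 features, sizes at which every documented property is already
  stable; the CLI default stays at n_boot = 9,999.

## Known limitations

* **CN couples null signs.** Because every sign of a feature shares the
  class-mean ratio, a null feature can become a spurious complete
  separator when that ratio drifts far enough — at the default noise
  settings roughly 2–6 per 10,000 null features, some of which also clear
  the 1.35 fold-change floor. The pair-resampling bootstrap cannot remove
  them (a zero-error feature is already at its minimal p). The
  independent-signs expectation M·2·0.5^N therefore applies to raw
  difference signs, not CN signs; the acceptance script reports the
  realized null selection count (`null_strict_selection_count`) so the
  effect is visible rather than hidden. Users screening for biomarkers
  should treat the fold-change floor and external validation, not the
  bootstrap, as the guard against this failure mode.
* The bootstrap-as-filter recipe is counting-based and insensitive to
  anything finer than the p-value's rank; it is not a confidence-interval
  bootstrap.
* Normal-approximation p-values are anti-conservative below n = 6; no
  exact mode is provided.
* The hypergeometric universe (13,074) and Bonferroni multiplier (22,283)
  are array-specific constants; users of other platforms must supply
  their own.
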