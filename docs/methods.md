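# Methods

This note records the modelling conventions, parameter defaults and
numerical choices behind `stemrisk`, and what the test suite does and does
not establish.

## Common structure

All three models share the same biological premise: cancer in a tissue is
initiated by the first single cell that accumulates `k` critical driver
mutations. Genes are exchangeable, mutations are irreversible, and
re-hits of an already-mutated gene are ignored (a re-hit would not change
the cell's mutation count, and at the per-division probabilities of
interest, 10⁻⁸–10⁻⁴, re-hits are vanishingly rare). Each mutation is
labelled by its source — "spontaneous" (all background mutagenic
processes) or induced by one specified mutagen — which is what makes the
attributable fraction `Pr_M` and relative risk `RR_M` well defined.

Mutagen exposure is modelled as late-onset: mutagen-associated rates are
zero early in the tissue's developmental history and constant afterwards,
emulating occupational or adult-life exposure. The onset default is one
third of the way through: division index `floor(N/3)` (that division
already exposed) in the division-indexed models, age `L_t/3 ≈ 26.7 y` in
the age-indexed branching model. The boundary placement — the onset
division itself exposed rather than the next one — is a deliberate
calibration: it is the convention that reproduces the published per-site
relative-risk and attributable-fraction tables at their printed precision,
and it matters only for tissues with few divisions (a relative shift of
order `k·u_M/(u_S·N)` in `RR_M`).

## Exact stem-lineage recurrence (`stemrisk.wu`)

* State: the joint probability table `P(S_g = s, M_g = m)`, `s + m ≤ k`,
  for one lineage. One division updates the `k−s−m` unmutated genes by a
  trinomial draw (spontaneous `u_S,i`, mutagen `u_M,i`, neither). The
  table is renormalised by construction and stays within 10⁻¹² of unit
  mass over thousands of divisions.
* Tissue aggregation: `2^n1` lineages are treated as independent, so
  `C_k = 1 − (1 − P_k)^(2^n1)` with `P_k = P(S_N + M_N = k)`. This is
  evaluated as `−expm1(2^n1 · log1p(−P_k))`, which keeps full relative
  precision for `P_k` down to 10⁻³⁰⁰ — necessary because per-site
  lifetime risks span more than 20 orders of magnitude.
* Independent oracle: because genes are i.i.d., the terminal distribution
  is also available in closed form as a multinomial over per-gene
  three-state absorbing-chain probabilities; the recurrence and the
  closed form agree to 10⁻¹² elementwise (property-tested over random
  rate schedules).
* Asymptotics: for small rates with onset at (almost exactly) `N/3` and
  `u_M = c·u_S`, per-gene first-event accounting gives
  `RR_M → (1 + 2c/3)^k` and `Pr_M → 1 − (3/(3+2c))^k`. The test suite
  asserts these within 1% on the long-division sites (N = 987, 1410,
  5868), where the exposed fraction of divisions is within O(1/N) of two
  thirds and no site is near risk saturation at the probing rate
  (u_S = 10⁻¹⁰); for short-division sites (N ≈ 30) the single extra
  exposed division at the onset boundary shifts `RR_M` by several percent
  and the limit formula is not informative.
* Rate schedules may differ arbitrarily by division (the symmetric /
  asymmetric distinction is representable), but the default schedule uses
  one constant spontaneous rate, following the position that there is no
  evidence the two division types mutate differently.

## Monte-Carlo tissue simulator (`stemrisk.frank`)

* Geometry: cycles are synchronous. At cycles `1..n1` the stem cell
  divides asymmetrically (daughter stem + transit-lineage root); every
  transit cell divides symmetrically until its lineage has completed `n2`
  divisions. All divisions within a cycle use pre-cycle states.
* Both daughters of every division are mutation-tested independently per
  remaining gene; the transit root is tested at transit rates and its new
  mutations are credited to the transit channel, while it inherits the
  stem-acquired mutations of its parent. A cell's state is the 4-way
  count (spontaneous/mutagen × stem/transit acquisition).
* Aggregation: cells are binned by (state, lineage age), so a replicate
  is a small integer matrix regardless of tissue size (2²⁰ cells for the
  default preset). Mutations are rare events, so each class samples the
  number of affected daughters binomially and only those are distributed
  multinomially over outcome states; both steps are vectorized across
  replicates. A 10,000-replicate run of the default tissue takes seconds
  to a few minutes depending on rates.
* Cancer labelling: all cells reaching `k` in the same cycle are counted
  and one labelling cell is chosen uniformly among them; this affects
  only the classification indicators, never `C_tot`. Conditional ratios
  with a zero denominator estimate are reported as NaN and printed "NA".
* Randomness: one generator drives each vectorized run, seeded from the
  configuration; the exposed and baseline runs of a relative-risk
  estimate use independent spawned streams. Runs are bit-reproducible
  given (seed, n_samples).
* Independent oracle: `enumerate_exact_small` propagates the full
  per-daughter outcome tree exactly for tiny tissues (≤ 16 daughter
  tests, `k ≤ 2`) including the labelling tie-break, and the simulator is
  checked against it within Monte-Carlo error, as well as against the
  `k = 1` closed-form no-cancer product on mid-sized tissues.

## Stochastic multistage branching model (`stemrisk.multistage`)

* Types `(α, β)`: α accumulated mutations, β stem (0) / transit (1).
  Per-cell rates: symmetric division `G`, death/differentiation `D`,
  asymmetric mutation `M` (parent persists, one daughter carries α+1),
  stem→stem+transit seeding `A`. A cell reaching `α = k` (stem) or
  `k_t` (transit; `k_t ∈ {k, k+1}`) is malignant and absorbing.
* Gestation (`[0, L_g]`, `L_g = 0.728 y`): `G(0,0) = ln(2^n1)/L_g`,
  `G(0,1) = 1 + G(0,0)`, `D = 0`, and `A(0,0)` chosen so the expected
  transit pool at birth is `p·2^n1` (`p = 0.01`). Mutated stem
  compartments seed transit cells at the same `A` during gestation.
* After birth all `G` and `D` are zero (approximately constant
  populations), and `A` is set to zero as well: a continuing gestational
  seeding rate with no transit death would grow the transit pool without
  bound, contradicting the constant-population premise. The
  intermediate-growth variant instead assigns `G = 1.1`, `D = 0.71`
  per cell per year to every compartment with ≥ 1 mutation.
* Mutation rates derive from per-division probabilities:
  `M(α,β) = d^α · [−n2 ln(1−u)/L_t]`. Mutagen increments add to `u`
  (before the `d^α` scaling) after the onset age; the stem-only /
  transit-only variants restrict the increment to one compartment.
  Defaults `u_stem = 10⁻⁸`, `u_transit = 10⁻⁶` (transit cells 100× the
  stem rate).
* Solution: backward Kolmogorov equations for the per-cell
  non-extinction probabilities, integrated piecewise over the rate
  regimes (gestation / pre-onset / post-onset) with LSODA at
  rtol 10⁻⁹. The complement `p = 1 − q` is integrated directly, so
  lifetime risks far below machine epsilon of 1 (e.g. 10⁻²²) are
  computed without cancellation.
* Independent oracle: an exact event-driven simulator of the same
  process (piecewise-constant rates handled by the advance-to-boundary
  construction, which is exact by memorylessness), vectorized across
  runs, guarded to `n1 ≤ 12`. The ODE solution is validated against it
  on small tissues, and the gestational branching means against
  `2^n1` and `p·2^n1`. The oracle cross-checks use inflated mutation
  probabilities (10⁻³–10⁻²) on a 16-stem-cell tissue so the compared
  probability is O(10⁻³–10⁻¹); at the biological 10⁻⁸ a desk-scale
  tissue has cancer probability ~10⁻¹⁰ and a 10⁵-run comparison would be
  vacuous.
* The published per-site table for this model depends on conventions its
  source leaves implicit (post-natal seeding, which products of an
  asymmetric division are at risk); under the minimal reading adopted
  here the computed values underestimate some printed entries, so those
  entries are treated as qualitative guidance and the Gillespie
  cross-validation is the module's correctness surface. The qualitative
  destabilization result is reproduced: at colorectal parameters with
  saturating baseline risk, `RR_M` decreases strictly as `d` grows
  through {0.5 … 1.5} (in the non-saturating regime `RR_M` is
  d-independent to first order, since the `d^α` factors cancel in the
  ratio — which is why the sweep is run at the saturating rates).

## Cross-site regressions (`stemrisk.regression`)

* `fit_trend` is ordinary least squares (statsmodels) with the slope
  F-test p-value, R², Pearson r and Spearman ρ (average ranks,
  two-sided). Influence is assessed by Cook's distance with the
  conventional threshold `4/(n − p − 1)` (`p = 2` fitted parameters);
  all flagged sites are removed in a single pass and the model refit
  once. Fewer than 3 complete pairs, or zero covariate variance, raise
  errors; in the batch runner such regressions are skipped with a logged
  warning.
* Log base: trends are reported against log₁₀(divisions); slope p-values,
  R² and both correlations are invariant to the base, only the slope
  itself rescales by ln 10.
* The radiation (REIC) and smoking covariates are externally supplied
  measurements; the package does not re-derive them. Reproducing the
  published cross-site correlation coefficients requires the
  supplementary per-site covariate table, which is not redistributed
  here; the pipeline is instead validated by exact recovery on noiseless
  synthetic covariates and by slope-coverage simulation.

## Synthetic data (`stemrisk.synthetic`)

The generators emulate a cross-site analysis table: ~31 sites, log₁₀
cumulative divisions uniform on 9–13, outcomes linear in the covariate
with Gaussian noise (default σ = 0.02 on a probability scale), and a
site table with division counts spanning the real registry's ranges.
They are bit-reproducible from their seed. What they deliberately do not
emulate: the strongly non-linear dependence of `Pr_M` on division count
across real sites, correlated measurement error in REIC, or missingness
patterns — so passing recovery tests demonstrates the estimator and
pipeline are correct, not that real covariates satisfy the linear model.

## Problem sizes used in the reproduction checks

Exact-recurrence site values are deterministic and instantaneous.
Monte-Carlo tissue probabilities use 10,000 replicates of the
n1 = 1024 / n2 = 10 tissue (binomial SE ≈ 0.003–0.007), matching the
precision of the published estimates. The branching-model
cross-validation uses a 2⁴-stem-cell tissue at 10⁵ exact-simulation runs;
gestational means use 5×10⁴ runs. These sizes make every check
informative at three standard errors while keeping the full suite around
a minute of compute.

## Known limitations

* The tissue simulator assumes equal stem and transit cycle times;
  differing cycle times are absorbed into the per-division rates.
* The recurrence model confines risk to stem lineages by construction;
  transit divisions enter only through the division count `N`.
* `k` identical exchangeable driver genes is a strong simplification;
  per-gene heterogeneous rates would require extending the state space.
* The branching model's post-natal constant-population reading is one of
  several defensible conventions (see above); absolute risks from that
  module are convention-sensitive even though risk ratios are stable.
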