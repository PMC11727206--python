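# Methods

## Model and estimand

Each of n units has covariates xᵢ ∈ ℝᵖ and two potential outcomes with
conditional means E[Y(t) | X] = f_t(xᵢ) and variances σ_t²(xᵢ), t ∈ {0, 1},
independent across units. The estimand is the finite-population average
treatment effect τ = n⁻¹ Σ (f₁(xᵢ) − f₀(xᵢ)); the estimator is the
difference in group means. Conditional on a fixed assignment T the MSE
decomposes as V + B with

    V = n₁⁻² Σ_{treated} σ₁²(xᵢ) + n₀⁻² Σ_{control} σ₀²(xᵢ),
    B = ( n₁⁻¹ Σ_{treated} f₁(xᵢ) − n₀⁻¹ Σ_{control} f₀(xᵢ) − τ )².

## Maximum risk and the kernel discrepancy

Nothing is assumed about f_t beyond membership in an RKHS ball:
(f_t, f_t)_Ω ≤ γ² for a symmetric reproducing kernel K, and σ_t² ≤ σ².
Over that class the worst-case MSE of a fixed assignment is

    R(T) = σ² (1/n₁ + 1/n₀) + γ² D_K(X₁, X₀)²,

where D_K is the kernel discrepancy (equivalently the maximum mean
discrepancy) between the treated and control empirical covariate
distributions, computed by the three-term Gram-sum expansion. An
equivalent subset-vs-full form uses D_K(X₁, X) + D_K(X₀, X); the two are
linked by the exact splitting identity D_K(X₁, X) + D_K(X₀, X) =
D_K(X₁, X₀) (the full sample's empirical CDF is the group-size-weighted
mixture of the two group CDFs), which the package verifies in tests and
uses as a cross-check inside `max_risk`.

The variance part of R(T) is minimized by any balanced assignment, so the
minimax design reduces to minimizing D_K over balanced partitions. Since
σ² and γ² only weight the two components, the minimizing partition does
not depend on them; they matter only when reporting the risk itself.

Two kernels are built in: the energy kernel −‖x − y‖₂ (its discrepancy is
the energy distance; domain ℝᵖ) and the centered-L2-discrepancy kernel
∏ⱼ (1 + ½|xⱼ−½| + ½|yⱼ−½| − ½|xⱼ−yⱼ|) on [0, 1]ᵖ. Arbitrary user kernels
are wrapped with a pointwise evaluator
(O(n²) kernel calls — intended for small n or discrete-covariate
discrepancies).

## Finding the optimal partition

* **Exhaustive oracle** (n ≤ 16): enumerates every unordered balanced
  split (C(n−1, n/2−1) for even n), ties broken lexicographically by the
  sorted treated-index tuple. Used as ground truth in tests.
* **Exchange descent**: from a seeded random balanced start, each pass
  evaluates all n₁·n₀ single swaps via O(1) incremental Gram-sum deltas,
  applies the best improving swap and then walks the remaining candidates
  of that pass in order of promise, applying those that still strictly
  improve (each is re-verified with an exact delta first, so the
  discrepancy is non-increasing and results are deterministic given the
  seed). The walk is capped at 1024 candidates per pass; anything missed
  reappears in the next pass's fresh sweep. Default `max_passes = 50`.
* **Twinning branch** (energy kernel): a nearest-neighbour pairing —
  allocate the current unit to one group and its nearest unallocated
  neighbour to the other, then hop to the nearest remaining unit — followed
  by the exchange polish. This is the default branch of the optimal-design
  dispatcher for the energy kernel and runs in ~0.3 s at n = 1000, p = 5.
* **CDF-transform branch** (unit-cube kernels): each covariate is mapped
  through its marginal empirical CDF (rank/n, average ranks on ties;
  constant columns degenerate with a warning), then exchange descent runs
  on the transformed points. The reported discrepancy is on the
  transformed scale.
* **Monte Carlo search** (any other kernel): best of M random balanced
  splits, default M = 500 — enough for the minimum to beat 99% of all
  candidates with probability 1 − 0.99⁵⁰⁰ > 99%.

Incremental swap updates agree with full recomputation to ~1e−13;
quadratic forms that round to tiny negatives (> −1e−10) are clamped to
zero before the square root, anything more negative raises. After the
square root this floating-point floor means "zero" discrepancies surface
as values up to ~3e−8 (e.g. on data sets where every point is duplicated).

For odd n the treated group receives ⌈n/2⌉ units in the partition
optimizers, while the randomized designs treat ⌊n/2⌋; the benchmark grid
uses even n throughout, where both conventions coincide. Which optimized
half receives treatment is a labeling choice; the package treats X₁*.

## Randomized baselines

* **CRE**: uniform draw from all assignments with fixed n₁ (default
  ⌊n/2⌋).
* **ReM**: redraws balanced CRE assignments until the Mahalanobis distance
  M = (n₁n₀/n)(x̄₁−x̄₀)ᵀ cov(X)⁻¹ (x̄₁−x̄₀) falls below the
  q-quantile of χ²_p (default q = 0.2, i.e. ~20% acceptance; M is
  asymptotically χ²_p under balanced CRE). The sample covariance uses the
  n−1 denominator; a singular covariance falls back to the pseudo-inverse
  with a warning. The control mean uses the standard n₀⁻¹ normalization.
  The variance-reduction multiplier
  v_a = P(χ²_{p+2} ≤ a)/P(χ²_p ≤ a) is exposed as `va_factor`.
* **Relaxed re-randomization**: accepts CRE draws whose kernel discrepancy
  is below the empirical α-quantile of the discrepancy's randomization
  distribution, estimated from `n_quantile_draws = 1000` Monte Carlo draws
  (the sampling budget is a package choice; quantile estimation error is
  of order (α(1−α)/1000)^½ in CDF units). α = 1 short-circuits to a plain
  CRE draw; rejection samplers give up after `max_draws = 1e5` attempts
  with a diagnostic.

## Estimation and risk utilities

`randomization_variance` returns the EV/VE decomposition of the CRE
randomization variance (EV = S²(f₁)/n₁ + S²(f₀)/n₀ − S²(f₁−f₀)/n from the
fixed potential outcomes, VE the average noise contribution);
`enumerate_assignment_moments` checks it exactly by enumerating all
C(n, n₁) assignments for n ≤ 14. The squared-bias term B above is read as
the square of the whole contrast minus τ (the only reading consistent with
the risk bound). Percent reduction, 100·(var_CRE − MSE_design)/var_CRE, is
computed in simulations from empirical MSEs over replications, not from
the analytic variance — the two differ by Monte Carlo error and the
empirical version is what the benchmark tables report.

## Simulation engine and what it does (not) show

`run_study` replicates one study cell: per replication it draws an n×p
covariate matrix (iid U[−3,3] or N(0, variance 3) — the "variance 3"
reading keeps the two laws moment-comparable), fits every configured
design on the same draw, draws one shared pair of unit-level N(0,1) noise
vectors, and records each design's squared estimation error and the
two-sample Kolmogorov–Smirnov distance between all n treated-arm potential
outcomes Y(1) and the observed outcomes of the treated group (the
"true-distribution" reading: the reference sample is all n values, not the
treated subset). Covariates are redrawn each replication by default —
without redrawing, the noiseless models C1/C3 would make the deterministic
design's error a constant rather than a distribution. Seeds derive from a
counter-based SeedSequence scheme so designs within a replication are
paired (same covariates and noise), which sharpens percent-reduction
comparisons. Identical configs reproduce identical results.

Built-in outcome models C1–C4 depend on covariates only through the row
mean x̃; they are smooth, low-effective-dimension functions. Passing the
benchmark therefore shows the design chain works under exactly these
conditions — it says nothing about heavy-tailed covariates, discrete
covariates (use a custom kernel), interference between units, or mean
functions outside the RKHS ball.

Benchmark problem sizes: the acceptance script runs the (C1/C2, p=5,
n=1000) and (C3, p=5, n=250) cells at 1000 replications and the (C1,
p=10, n=2000) cell at 250 replications; the test suite re-checks the main
cell at 400 replications and the n=2000 cell at 60 — replication counts
are chosen so the whole suite stays desk-scale, with Monte Carlo standard
errors always computed from the replications actually run.

## Known limitations

* The exchange heuristic finds local minima of the swap neighbourhood; at
  n = 1000 (p = 5, U[−3,3] covariates) the achieved energy distance is
  ~0.055 versus ~0.14 for a random split, but no global-optimality claim
  is made beyond the n ≤ 16 oracle regime.
* Deterministic assignment forfeits randomization inference; only
  asymptotic or model-based inference applies. The relaxed re-randomized
  variant restores a randomization distribution at a small cost in
  balance.
* `UserKernel` evaluation is pure Python and quadratic in n.
* Multi-arm designs and sequential/adaptive allocation are out of scope.
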