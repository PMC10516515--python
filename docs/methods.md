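# Methods

## The attack model

A federation consists of `n_h` data-owning servers; server `j` holds a
matrix `X_j` with `n_j` observations (rows) of `n_p` variables
(columns).  The analyst ("client" in DataSHIELD's naming; the data
owners are "servers") can only call three primitives that essentially
every federated-statistics platform exposes:

* **T1** `Mean(x)` — sample mean of a server-side vector;
* **T2** `Cov(x, y)` — sample covariance with denominator `n − 1`;
* **T3** broadcast — send a client-known matrix to a server, after which
  its columns are addressable server-side vectors.

The covariance of the target `x` with a known probe `y_i` is one linear
equation in the entries of `x`:

    Cov(x, y_i) = (1/(n−1)) y_iᵀ x − (n/(n−1)) Mean(x) Mean(y_i).

Broadcasting an `n × n` matrix `Y` of linearly independent probes and
querying the `n` covariances `Ṽ_i = Cov(x, y_i)` plus the single mean
`Mean(x)` gives the full-rank system

    Yᵀ x = (n−1) Ṽ + n · Mean(x) · m̃,        m̃_i = Mean(y_i),

whose solution is the private vector, using `n + 1` server queries per
variable (probe means are client-side).  Communication is therefore
linear in `n_j`; the `O(n_j³)` dense solve is negligible at the sample
sizes of biomedical federations.  A Krylov-subspace solver would extend
the method to very large `n_j`; it is not implemented here.

Standard-normal probes are the default: their columns are linearly
independent almost surely, and each probe has `n` distinct values, so it
can never be classified as dichotomous by a level-count disclosure rule.
An orthonormalised probe mode (`ProbeMatrix.orthonormalized`) exists for
ill-conditioned regimes but is off by default.

### Numerical choices

* The system is solved by LU factorisation of `Yᵀ` (never an explicit
  inverse), with the factorisation cached on the `ProbeMatrix` so that
  repeated attacks (noise averaging, sweeps) pay for it once.
* The mean term is moved out of the solve using the exact identity
  `Yᵀ 1 = n m̃`, i.e. `x̂ = (n−1)(Yᵀ)⁻¹Ṽ + Mean(x)·1`.  This is
  algebraically identical to solving the full right-hand side but keeps
  the large mean offset (≈27 for a BMI-like column) out of the
  factorisation; empirically it reduces the attainable max abs error at
  `n = 250` from a few `1e−12` to a few `1e−13`.
* Probe generation checks numerical rank (smallest singular value
  `> 1e−8 ×` the largest) and redraws from a derived sub-seed on the
  measure-zero failure event, at most 8 times.
* Covariances are computed with the two-pass (centred) formula.

### Regression side channel

Platforms that expose linear-model fits rather than a covariance
endpoint leak the same information: the slope of `x = y·β + ε` with a
broadcast probe as regressor is `β̂ = Cov(x, y)/Var(y)`, and `Var(y)` is
client-known, so `Cov(x, y) = β̂·Var(y)` exactly.  The package routes
the attack through either channel (`channel="cov" | "regression"`); the
two reconstructions agree to numerical precision.  The regression
endpoint applies no minimum-count disclosure checks, mirroring the
deep-learning-oriented platforms it models.

## Disclosure rules

`DisclosurePolicy` mirrors DataSHIELD's defaults: a mean is released
only when `n > 3`, a covariance only when `n > 6` (strict thresholds),
and every vector classified as dichotomous (exactly two distinct
values) must have each level occur at least 3 times — applied to data
columns *and* probes.  Refusals are raised before any value is computed
and are recorded in the query log with `status="refused"`.

The sample-size rule is monotone: refusal at `n` implies refusal at any
smaller `n` under the same policy.  The level-count rule is not monotone
in `n` in general, because classification depends on the data (any
2-observation vector with distinct values counts as dichotomous); the
property tests treat the two rules separately.

Missing cells (`NaN`) are handled by listwise complete-case analysis on
the vectors a query references; the effective `n` in all formulas and
checks is the complete-case count.  Attacks on columns with missingness
target the complete-case subset (`Federation.complete_case_view`), the
same pre-processing an analyst would apply.

## Noise averaging

If the server adds zero-mean noise `ε_i` to covariances and `γ` to the
mean, the reconstruction decomposes exactly as

    x_noisy = x + (n−1)(Yᵀ)⁻¹ε + n·γ·(Yᵀ)⁻¹m̃,

so `x_noisy` is unbiased for `x`, and the average of `R` independent
noisy reconstructions (noise redrawn per repetition, probes held fixed
— the estimator averages over noise, not probes) has MSE proportional
to `1/R` (convergence in probability at rate `√R`).

The experiment driver sweeps noise levels × repetition counts ×
replicates and reports the median and 5th/95th percentiles of the
**relative MSE**, defined as MSE divided by the sample variance of the
true vector.  Noise levels are relative: level `l` perturbs both
endpoints with sd `l × sd(x)`.  Defaults: levels {0.01, 0.1, 1, 10},
`R ∈ {1, 10, 100}`, 200 replicates — chosen as the package's study
conditions; tests scale the replicate count down where a cruder check
suffices.

## Differential-privacy accounting

The Laplace mechanism releases a statistic with worst-case sensitivity
`Δ` plus Laplace(scale `b`) noise and consumes `ε = Δ/b`.  Charges
compose additively; one attack iteration costs

    ε_att = Σ_i ε_cov(x, y_i) + ε_mean(x),

and a total budget `ε_A` admits `⌊ε_A/ε_att⌋` iterations.  The
accountant refuses (and withholds the answer of) any query whose charge
would exceed the budget.

Sensitivities assume each data variable is clipped to configured bounds
`[a, b]` (width `w`), with neighbouring datasets differing by one
record's replacement inside the clip box:

* mean: `w/n`;
* covariance with a *public* probe (broadcast, client-known — not part
  of any protected record): the sample covariance is linear in `x`, so
  exactly `w · max_s|y_s − ȳ| / (n−1)`;
* covariance of two data variables: the exact change under one-record
  replacement is multi-affine in the six free quantities (old and new
  record values and the means of the untouched records), so its extreme
  over the clip boxes is attained at one of 64 vertices, each of which
  is a realisable dataset — the enumeration is therefore exact, and the
  test suite confirms it by brute force;
* variance (a variable with itself): quadratic rather than affine in
  the old record value, so the interior stationary point joins the
  vertex candidates.

Probe-only statistics are free (`ε = 0`, no noise): differential privacy
protects the dataset, not public inputs.  Only simple sequential
composition is used, matching the additive budget formula above; no
advanced or Rényi composition.

### Trade-off experiments

The attack-versus-budget experiment sweeps a 4-point log-spaced budget
grid spanning the conventional range `[ln 1.01, ln 3]` against Laplace
noise scales `{500, 2000, 8000, 32000}` (at the default `n = 30`–`50`
and a clip width of 35 these span zero admissible iterations up to
several hundred).  Per cell it computes the admissible iteration count
from the actual probe sensitivities, runs the noise-averaged attack with
exactly that many iterations, and reports the median relative MSE over
replicates.  Probes are drawn once per replicate and shared across all
cells, which makes the iteration counts exactly monotone (nondecreasing
in noise scale at fixed budget, nondecreasing in budget at fixed scale)
within each replicate; a replicate that cannot afford one iteration
reconstructs nothing and enters the summary as infinite relative MSE.

More noise per release ⇒ cheaper queries ⇒ more iterations for the same
budget, and in general better attack accuracy at a fixed budget — but
even at the largest scale the admissible iteration counts stay orders
of magnitude short of averaging the noise away: the DP-limited attack
error exceeds the noiseless attack's error by many orders of magnitude.

The standard-analysis workflows (means, variances and the covariance of
two metric variables; all pairwise covariances among five metric
variables) are metered at *analysis-grade* noise scales `{1, 5, 10, 50}`
— magnitudes at which the released statistics retain utility.  There
the data–data covariance sensitivity (≈ `w_x w_y` scale divided by
`n−1`) makes a single covariance consume a large fraction of, or the
entire, `ln 3` budget: the same mechanism that blocks the attack also
precludes routine descriptive analysis.

## Synthetic federations

The generator emulates the *structure* of the CNSIM tutorial federation:
3 servers with 2163/3088/4128 observations (9379 total) of 11 variables
— five continuous (a BMI-like column `Normal(27, 4²)` clipped to
`[15, 50]`, plus cholesterol-, triglyceride-, HDL- and glucose-like
columns) and six dichotomous indicators (Bernoulli with prevalences
0.04–0.5, both levels forced to occur ≥ 3 times whenever `n ≥ 6`, so the
level-count rule is satisfiable by construction).  Missing cells are
injected completely at random at a configurable rate (default 0).  All
draws flow from a single seed; CSV output is byte-identical across runs.

What the generator does **not** emulate: the real CNSIM marginals and
correlations (not public), realistic cross-variable dependence,
non-normal marginals, or informative missingness.  None of these affect
the attack's algebra — reconstruction is exact for *any* data — so
passing tests on synthetic data transfer to real data for the noiseless
claims; the noise/DP experiment *levels* are relative to the data scale
and would need re-tuning per dataset.  A loader for user-supplied CNSIM
CSV exports is provided; the data themselves are not redistributed.

## Problem sizes used in tests

Exactness is verified at `n ∈ {3, …, 250}`; the noise-averaging rate at
`n = 50` with `R ≤ 100` and 200 replicates; the DP grid at `n = 30` with
12 replicates.  These are the package's chosen study scales; all
qualitative claims are scale-free and the key quantitative ones
(reconstruction error, `1/R` rate) are checked at the sizes above.

## Known limitations

* No networking or real client/server processes; the federation is
  in-process and single-threaded.
* No Krylov-subspace solver for very large `n_j`.
* Sequential composition only; advanced composition would sharpen the
  budget arithmetic in the analyst's favour.
* The DP noise scales required to see the trade-off depend on the clip
  width and `n`; the defaults match the shipped synthetic federations.
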