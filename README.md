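# covleak

**Reconstruction-risk auditing for federated analysis platforms that
expose sample means and covariances.**

Federated analysis platforms (DataSHIELD and its relatives, federated
deep-learning frameworks) promise that data owners share only
"non-disclosive" summary statistics with a central analyst.  `covleak`
demonstrates — and lets platform developers measure — how little that
promise can mean: an analyst who can (T1) request sample means,
(T2) request sample covariances against vectors of their choosing, and
(T3) send known matrices to a server can reconstruct the private data
**exactly**.

For a target vector `x ∈ ℝⁿ` and client-known linearly independent
probes `y₁, …, yₙ` (columns of `Y`), each released covariance is a
linear equation in `x`:

    Cov(x, yᵢ) = (1/(n−1)) yᵢᵀx − (n/(n−1)) · Mean(x) · Mean(yᵢ)

so `n` covariance queries plus one mean query give the full-rank system

    Yᵀx = (n−1)·Ṽ + n·Mean(x)·m̃

whose solution is the private data, at a cost of `n + 1` queries per
variable.  The package provides:

* **`covleak.testbed`** — an in-process mock federation: servers holding
  private matrices behind mean/covariance/broadcast endpoints, with
  DataSHIELD-style disclosure thresholds (mean released only for
  `n > 3`, covariance for `n > 6`, dichotomous levels ≥ 3), optional
  additive output noise, a privacy accountant, and an auditable query
  log.
* **`covleak.attack`** — probe generation and the covariance-based
  reconstruction, per variable or as a full-federation sweep, including
  the regression side channel `Cov(x, y) = β̂·Var(y)` for platforms that
  expose linear-model fits instead of covariances.
* **`covleak.noise_averaging`** — the defence-by-noise analysis: output
  noise is zero-mean, so averaging `R` repeated attacks drives the MSE
  down like `1/R`.
* **`covleak.dp`** — an ε-differential-privacy accountant (Laplace
  mechanism, additive composition) with worst-case sensitivities for
  clipped means/covariances, plus the budget-versus-accuracy trade-off
  experiments showing that budgets tight enough to stop the attack also
  price routine descriptive statistics out of reach.
* **`covleak.synthetic`** — a generator for CNSIM-like federations
  (3 servers, 9379 observations, 11 mixed continuous/dichotomous
  obesity-related variables) so every experiment runs with no download,
  and a loader for user-supplied CNSIM CSV exports.

## Worked example

Attack a synthetic single-server federation with 250 observations:

```sh
covleak attack --config demo.yaml --seed 1 --out demo_out
covleak report demo_out
```

with `demo.yaml` containing

```yaml
federation:
  n_per_server: [250]
```

prints

```
reconstructed 11 variables (0 refused); report in demo_out
command: attack  seed: 1
n_reconstructed: 11
n_refused: 0
total_queries: 2762
  server1/bmi: r = 1.0000000000, max |error| = 5.222e-13
  server1/cholesterol_total: r = 1.0000000000, max |error| = 9.592e-14
  ...
```

Every variable — the analyst never saw a single raw value — comes back
with Pearson correlation 1.0 against the truth and elementwise errors
at the 10⁻¹³ level: the attack is exact up to floating-point rounding.
The query log (`demo_out/query_log.jsonl`) shows 251 queries per
variable (250 covariances + 1 mean), the linear-in-`n` communication
cost.  The same run is available from Python:

```python
from covleak import Federation, FederationSpec, generate_federation, reconstruct_variable

servers, truth = generate_federation(FederationSpec(n_per_server=(250,)))
fed = Federation(servers)
res = reconstruct_variable(fed, "server1", "bmi", seed=1)
print(res.error_metrics)   # pearson_r = 1.0, max_abs_error ~ 5e-13
```

Other commands: `covleak simulate-data` (write the synthetic CSVs),
`covleak attack-noisy` (MSE-versus-repetitions robustness experiment),
`covleak dp-experiment` (privacy-budget trade-off tables).

## Scope

The federation is in-process: no networking, no bindings to DataSHIELD,
TensorFlow Federated, or other platforms.  The package is a design-audit
tool for endpoint surfaces, not an attack tool against deployments.
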