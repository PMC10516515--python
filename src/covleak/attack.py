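"""Covariance-based reconstruction of private server-side vectors.

The attack exploits the algebra of the sample covariance.  For a target
vector ``x`` of length ``n`` and any client-known probe ``y_i``,

    Cov(x, y_i) = (1/(n-1)) y_i^T x - (n/(n-1)) Mean(x) Mean(y_i),

so each released covariance is one linear equation in the unknown
entries of ``x``.  Broadcasting ``n`` linearly independent probes
``Y = (y_1 ... y_n)`` and querying the ``n`` covariances plus the single
mean of ``x`` yields the full-rank system

    Y^T x = (n-1) * V + n * Mean(x) * m,

with ``V`` the vector of released covariances and ``m`` the client-side
probe means.  Solving it recovers ``x`` to numerical precision.  The
total cost is ``n`` covariance queries and one mean query per variable —
linear communication in the sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, lu_factor, lu_solve

from .errors import DegenerateProbe, DisclosureRefused, ProbeDegenerate, SingularProbe
from .testbed import Federation

__all__ = [
    "ProbeMatrix",
    "ReconstructionResult",
    "SweepResult",
    "generate_probes",
    "reconstruct_variable",
    "reconstruct_all",
    "covariance_from_regression",
]

#: rank tolerance, relative to the spectral norm of the probe matrix
_RANK_RTOL = 1e-8
#: bounded redraw attempts before giving up on probe generation
_MAX_REDRAWS = 8


class ProbeMatrix:
    """An ``n x n`` client-known matrix of linearly independent probes.

    Column ``i`` is the probe ``y_i``.  The client keeps an identical
    copy of what it broadcasts, so probe means and variances are free,
    client-side quantities.  An LU factorisation of ``Y^T`` is cached so
    repeated reconstructions (noise averaging, sweeps) pay for one
    factorisation only.
    """

    def __init__(self, Y: np.ndarray, rng_seed: int | None = None) -> None:
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != Y.shape[1]:
            raise ValueError("probe matrix must be square")
        if not _numerically_full_rank(Y):
            raise SingularProbe("probe matrix is numerically rank deficient")
        self.Y = Y
        self.rng_seed = rng_seed
        self.condition_estimate = float(np.linalg.cond(Y))
        self._lu = None

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def means(self) -> np.ndarray:
        """Client-side probe means ``m`` (no server query required)."""
        return self.Y.mean(axis=0)

    @property
    def variances(self) -> np.ndarray:
        """Client-side probe sample variances (denominator ``n - 1``)."""
        return self.Y.var(axis=0, ddof=1)

    def solve_transposed(self, rhs: np.ndarray) -> np.ndarray:
        """Solve ``Y^T z = rhs`` via the cached LU factorisation."""
        if self._lu is None:
            try:
                self._lu = lu_factor(self.Y.T)
            except LinAlgError as exc:  # pragma: no cover - guarded by rank check
                raise SingularProbe(str(exc)) from exc
        return lu_solve(self._lu, rhs)

    def orthonormalized(self) -> "ProbeMatrix":
        """QR-orthonormalised variant (condition number 1) for
        ill-conditioned regimes; plain normal probes remain the default."""
        q, _ = np.linalg.qr(self.Y)
        return ProbeMatrix(q, rng_seed=self.rng_seed)


def _numerically_full_rank(Y: np.ndarray) -> bool:
    s = np.linalg.svd(Y, compute_uv=False)
    return bool(s[-1] > _RANK_RTOL * s[0])


def generate_probes(n: int, seed: int | None = None) -> ProbeMatrix:
    """Draw an ``n x n`` standard-normal probe matrix.

    Independent standard-normal entries make the columns linearly
    independent almost surely, and give each probe ``n`` distinct values
    so the minimum-level-count disclosure rule for dichotomous vectors
    never triggers.  On the (measure-zero) event of numerical rank
    deficiency the matrix is redrawn from a derived sub-seed, up to a
    bounded number of attempts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = np.random.SeedSequence(seed)
    for child in seq.spawn(_MAX_REDRAWS):
        rng = np.random.default_rng(child)
        Y = rng.standard_normal((n, n))
        if _numerically_full_rank(Y):
            return ProbeMatrix(Y, rng_seed=seed)
    raise ProbeDegenerate(
        f"no full-rank {n}x{n} probe matrix after {_MAX_REDRAWS} draws"
    )


@dataclass
class ReconstructionResult:
    """Outcome of one single-variable attack."""

    x_hat: np.ndarray
    V_tilde: np.ndarray
    m_tilde: np.ndarray
    mean_x: float
    target: tuple[str, str]
    channel: str = "cov"
    n_queries: int = 0
    error_metrics: dict[str, float] | None = None

    @property
    def n(self) -> int:
        return int(self.x_hat.size)

    def score(self, truth: np.ndarray) -> dict[str, float]:
        """Error metrics of the reconstruction against a known truth."""
        truth = np.asarray(truth, dtype=float)
        resid = self.x_hat - truth
        var = float(np.var(truth, ddof=1))
        mse = float(np.mean(resid**2))
        if np.std(truth) > 0 and np.std(self.x_hat) > 0:
            r = float(np.corrcoef(truth, self.x_hat)[0, 1])
        else:
            r = float("nan")
        self.error_metrics = {
            "max_abs_error": float(np.max(np.abs(resid))),
            "mse": mse,
            "relative_mse": mse / var if var > 0 else float("inf"),
            "pearson_r": r,
        }
        return self.error_metrics


def covariance_from_regression(beta_hat: float, var_y: float) -> float:
    """Recover ``Cov(x, y) = beta_hat * Var(y)`` from a released simple
    linear-regression slope and the client-known probe variance."""
    if var_y <= 0.0:
        raise DegenerateProbe("probe variance must be positive")
    return float(beta_hat) * float(var_y)


def _collect_covariances(
    fed: Federation,
    server_id: str,
    variable: str,
    probes: ProbeMatrix,
    probe_name: str,
    channel: str,
) -> np.ndarray:
    n = probes.n
    V = np.empty(n)
    if channel == "cov":
        for i in range(n):
            V[i] = fed.query_cov(server_id, variable, f"{probe_name}[{i}]")
    elif channel == "regression":
        var_y = probes.variances
        for i in range(n):
            beta = fed.query_regression_coefficient(
                server_id, variable, f"{probe_name}[{i}]"
            )
            V[i] = covariance_from_regression(beta, var_y[i])
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return V


def reconstruct_variable(
    fed: Federation,
    server_id: str,
    variable: str,
    probes: ProbeMatrix | None = None,
    seed: int | None = None,
    channel: str = "cov",
    probe_name: str | None = None,
    score: bool = True,
) -> ReconstructionResult:
    """Run the covariance-based attack against one variable.

    Issues exactly ``n`` covariance (or regression-slope) queries and one
    mean query against the target server; probe means are computed
    client-side from the broadcast copy.  When ``probes`` is ``None`` a
    fresh standard-normal probe matrix is drawn from ``seed``.  If
    ``probes`` is given and already broadcast under ``probe_name``, the
    broadcast is reused (``reconstruct_all`` relies on this).

    With ``score=True`` (an audit-side convenience: the testbed holds the
    ground truth) the result carries error metrics of the reconstruction.
    """
    server = fed.server(server_id)
    n = server.n_obs
    if probes is None:
        probes = generate_probes(n, seed)
    if probes.n != n:
        raise SingularProbe(
            f"probe matrix is {probes.n}x{probes.n} but server holds {n} observations"
        )
    if probe_name is None:
        probe_name = f"_probe_{variable}"
        fed.broadcast(server_id, probe_name, probes.Y)
    elif probe_name not in server.broadcast_store:
        fed.broadcast(server_id, probe_name, probes.Y)

    queries_before = len(fed.log)
    V = _collect_covariances(fed, server_id, variable, probes, probe_name, channel)
    mean_x = fed.query_mean(server_id, variable)
    m = probes.means

    # Y^T x = (n-1) V + n Mean(x) m.  The mean term satisfies
    # Y^T 1 = n m exactly, so it can be moved out of the solve:
    # x = (n-1) (Y^T)^{-1} V + Mean(x) 1.  Algebraically identical,
    # but it keeps the large mean offset out of the factorisation and
    # roughly halves the attainable reconstruction error.
    x_hat = (n - 1) * probes.solve_transposed(V) + mean_x
    if not np.all(np.isfinite(x_hat)):
        raise SingularProbe("solve produced non-finite entries")

    result = ReconstructionResult(
        x_hat=x_hat,
        V_tilde=V,
        m_tilde=m,
        mean_x=mean_x,
        target=(server_id, variable),
        channel=channel,
        n_queries=len(fed.log) - queries_before,
    )
    if score:
        truth = fed.server(server_id).column(variable)
        if np.all(np.isfinite(truth)):
            result.score(truth)
    return result


@dataclass
class SweepResult:
    """Full-federation attack: per-variable results plus refusals."""

    results: list[ReconstructionResult] = field(default_factory=list)
    refusals: list[tuple[str, str, str]] = field(default_factory=list)

    def summary(self):
        """Tidy per-variable error table (requires scored results)."""
        import pandas as pd

        rows = []
        for res in self.results:
            row = {
                "server_id": res.target[0],
                "variable": res.target[1],
                "n": res.n,
                "n_queries": res.n_queries,
            }
            if res.error_metrics:
                row.update(res.error_metrics)
            rows.append(row)
        for sid, var, reason in self.refusals:
            rows.append(
                {"server_id": sid, "variable": var, "n": None, "refused": reason}
            )
        return pd.DataFrame(rows)


def reconstruct_all(
    fed: Federation,
    probe_reuse: bool = True,
    seed: int | None = None,
    channel: str = "cov",
) -> SweepResult:
    """Sweep every server and variable of the federation.

    With ``probe_reuse=True`` one probe matrix is generated and broadcast
    per server and shared by all its variables (a single broadcast, then
    ``n_j`` covariance + 1 mean query per variable).  Variables refused
    by the disclosure policy are recorded, not fatal.
    """
    seq = np.random.SeedSequence(seed)
    sweep = SweepResult()

    def _sub_seed(ss: np.random.SeedSequence) -> int:
        return int(ss.spawn(1)[0].generate_state(1, dtype=np.uint32)[0] >> 1)

    for sid, child in zip(fed.server_ids, seq.spawn(len(fed.servers))):
        server = fed.server(sid)
        probes = generate_probes(server.n_obs, _sub_seed(child))
        probe_name: str | None = None
        for var in server.variable_names:
            col = server.column(var)
            has_missing = not np.all(np.isfinite(col))
            try:
                if has_missing:
                    # attack the complete-case subset with its own probes
                    view = fed.complete_case_view(sid, [var])
                    sub = generate_probes(view.server(sid).n_obs, _sub_seed(child))
                    res = reconstruct_variable(
                        view, sid, var, probes=sub, channel=channel
                    )
                else:
                    if not probe_reuse:
                        probes = generate_probes(server.n_obs, _sub_seed(child))
                        probe_name = None
                    if probe_name is None:
                        probe_name = (
                            f"_sweep_probe_{sid}" if probe_reuse else f"_probe_{var}"
                        )
                        fed.broadcast(sid, probe_name, probes.Y)
                    res = reconstruct_variable(
                        fed, sid, var, probes=probes, channel=channel,
                        probe_name=probe_name,
                    )
                sweep.results.append(res)
            except DisclosureRefused as exc:
                sweep.refusals.append((sid, var, str(exc)))
    return sweep
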