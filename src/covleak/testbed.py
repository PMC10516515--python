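"""In-process mock of a federated analysis infrastructure.

A federation consists of ``n_h`` data-owning servers, each holding a
private matrix ``X_j`` (``n_j`` observations by ``n_p`` variables).  The
analyst ("client") never sees raw data; the only channels are the three
primitives that virtually every federated-statistics platform exposes:

* a sample-mean endpoint,
* a sample-covariance endpoint (denominator ``n - 1``),
* a broadcast primitive that ships a client-known matrix to a server,
  after which its columns are addressable as server-side vectors.

Each endpoint enforces DataSHIELD-style disclosure rules (minimum sample
sizes for mean/covariance releases, minimum per-level counts for
dichotomous variables), may perturb its answer with zero-mean additive
noise, and may be metered by an :class:`~covleak.dp.PrivacyAccountant`.
Every call is appended to an auditable query log, so the testbed doubles
as a disclosure-audit demonstration: the full transcript of an attack is
available for inspection.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateProbe,
    DisclosureRefused,
    InvalidParameter,
    LengthMismatch,
    ShapeMismatch,
    UnknownVariable,
)

if TYPE_CHECKING:  # pragma: no cover
    from .dp import PrivacyAccountant

__all__ = [
    "Variable",
    "ServerDataset",
    "DisclosurePolicy",
    "NoisePolicy",
    "QueryRecord",
    "QueryLog",
    "Federation",
    "query_mean",
    "query_cov",
    "broadcast",
    "query_regression_coefficient",
]

VariableKind = Literal["continuous", "dichotomous"]

_BROADCAST_REF = re.compile(r"^(?P<name>.+)\[(?P<index>\d+)\]$")


@dataclass(frozen=True)
class Variable:
    """Metadata for one column of a server's data matrix."""

    name: str
    kind: VariableKind = "continuous"


def infer_kind(values: np.ndarray) -> VariableKind:
    """Classify a vector as dichotomous iff it has exactly two distinct
    finite values; anything else counts as continuous."""
    finite = values[np.isfinite(values)]
    return "dichotomous" if np.unique(finite).size == 2 else "continuous"


class ServerDataset:
    """One data owner: a private matrix plus the vectors it has received.

    Parameters
    ----------
    server_id:
        Identifier of the data owner.
    data:
        Observations in rows, variables in columns.  ``NaN`` marks a
        missing cell; endpoints operate on complete cases of the columns
        they reference.
    variables:
        Optional explicit per-column metadata.  When omitted, each column
        is classified by :func:`infer_kind`.
    """

    def __init__(
        self,
        server_id: str,
        data: pd.DataFrame,
        variables: Sequence[Variable] | None = None,
    ) -> None:
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("server data must have at least one row and one column")
        self.server_id = str(server_id)
        self.data = data.astype(float)
        if variables is None:
            variables = [
                Variable(str(c), infer_kind(self.data[c].to_numpy()))
                for c in self.data.columns
            ]
        else:
            names = [v.name for v in variables]
            if names != [str(c) for c in data.columns]:
                raise ValueError("variable metadata does not match data columns")
            for v in variables:
                if v.kind == "dichotomous":
                    col = self.data[v.name].to_numpy()
                    if np.unique(col[np.isfinite(col)]).size != 2:
                        raise ValueError(
                            f"column {v.name!r} flagged dichotomous but does not "
                            "have exactly two distinct values"
                        )
        self.variables: list[Variable] = list(variables)
        self.broadcast_store: dict[str, np.ndarray] = {}

    @property
    def n_obs(self) -> int:
        """Number of observation rows ``n_j`` (before complete-case masking)."""
        return int(self.data.shape[0])

    @property
    def n_vars(self) -> int:
        return int(self.data.shape[1])

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise UnknownVariable(name)
        return self.data[name].to_numpy()

    def resolve(self, ref: str) -> tuple[np.ndarray, bool]:
        """Return ``(vector, is_broadcast)`` for a reference.

        A reference is either a column name of the data matrix or
        ``"<name>[<i>]"`` addressing the ``i``-th column (0-based) of a
        previously broadcast matrix.
        """
        m = _BROADCAST_REF.match(ref)
        if m and m.group("name") in self.broadcast_store:
            mat = self.broadcast_store[m.group("name")]
            idx = int(m.group("index"))
            if idx >= mat.shape[1]:
                raise UnknownVariable(ref)
            return mat[:, idx], True
        if ref in self.data.columns:
            return self.data[ref].to_numpy(), False
        raise UnknownVariable(ref)

    def complete_case_view(self, variables: Iterable[str]) -> "ServerDataset":
        """A new dataset restricted to rows with no missing value in
        ``variables``.  The broadcast store starts empty."""
        cols = list(variables)
        for c in cols:
            if c not in self.data.columns:
                raise UnknownVariable(c)
        mask = self.data[cols].notna().all(axis=1).to_numpy()
        return ServerDataset(self.server_id, self.data.loc[mask].reset_index(drop=True))


@dataclass(frozen=True)
class DisclosurePolicy:
    """Server-side answer rules, mirroring DataSHIELD's defaults.

    ``mean_min_n`` / ``cov_min_n`` are *strict* lower bounds: a mean is
    released only when ``n > mean_min_n`` and a covariance only when
    ``n > cov_min_n``.  ``dichotomous_min_level_count`` is the minimum
    number of occurrences of each level of a dichotomous vector.
    """

    mean_min_n: int = 3
    cov_min_n: int = 6
    dichotomous_min_level_count: int = 3
    enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.mean_min_n, self.cov_min_n, self.dichotomous_min_level_count) < 0:
            raise InvalidParameter("disclosure thresholds must be nonnegative")

    def check_mean(self, vec: np.ndarray) -> None:
        self._check(vec, self.mean_min_n, "mean")

    def check_cov(self, vec: np.ndarray) -> None:
        self._check(vec, self.cov_min_n, "covariance")

    def _check(self, vec: np.ndarray, min_n: int, endpoint: str) -> None:
        if not self.enabled:
            return
        n = int(vec.size)
        if n <= min_n:
            raise DisclosureRefused(
                f"{endpoint} refused: n = {n} does not exceed the threshold {min_n}"
            )
        # a vector is dichotomous iff every entry equals its min or its max
        # (and they differ); O(n) with no sort, exact
        vmin, vmax = vec.min(), vec.max()
        if vmin != vmax:
            c_lo = int(np.sum(vec == vmin))
            c_hi = int(np.sum(vec == vmax))
            if c_lo + c_hi == n and min(c_lo, c_hi) < self.dichotomous_min_level_count:
                raise DisclosureRefused(
                    f"{endpoint} refused: a dichotomous level occurs "
                    f"{min(c_lo, c_hi)} < {self.dichotomous_min_level_count} times"
                )


@dataclass(frozen=True)
class NoisePolicy:
    """Additive zero-mean output perturbation applied by the server.

    ``sd == 0`` reproduces noiseless answers bit-for-bit (no generator
    draw is consumed).  For the Laplace distribution the scale parameter
    is ``sd / sqrt(2)`` so that ``sd`` always denotes the standard
    deviation of the perturbation.
    """

    mean_noise_sd: float = 0.0
    cov_noise_sd: float = 0.0
    distribution: Literal["gaussian", "laplace"] = "gaussian"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_noise_sd < 0 or self.cov_noise_sd < 0:
            raise InvalidParameter("noise standard deviations must be nonnegative")
        if self.distribution not in ("gaussian", "laplace"):
            raise InvalidParameter(f"unknown noise distribution {self.distribution!r}")

    @property
    def mean_scale(self) -> float:
        """Laplace scale ``b`` of the mean perturbation (sd / sqrt(2))."""
        return self.mean_noise_sd / math.sqrt(2.0)

    @property
    def cov_scale(self) -> float:
        """Laplace scale ``b`` of the covariance perturbation."""
        return self.cov_noise_sd / math.sqrt(2.0)

    @classmethod
    def laplace_from_scales(
        cls, mean_scale: float, cov_scale: float, rng_seed: int = 0
    ) -> "NoisePolicy":
        """Build a Laplace policy from Laplace scale parameters ``b``
        (the natural parametrisation of the privacy mechanism)."""
        s = math.sqrt(2.0)
        return cls(mean_scale * s, cov_scale * s, "laplace", rng_seed)

    def draw(self, rng: np.random.Generator, sd: float) -> float:
        if sd == 0.0:
            return 0.0
        if self.distribution == "gaussian":
            return float(rng.normal(0.0, sd))
        return float(rng.laplace(0.0, sd / math.sqrt(2.0)))


@dataclass(frozen=True)
class QueryRecord:
    server_id: str
    endpoint: str
    args: str
    epsilon: float = 0.0
    status: str = "ok"


class QueryLog:
    """Append-only transcript of every endpoint call in a federation."""

    def __init__(self) -> None:
        self._records: list[QueryRecord] = []

    def append(self, record: QueryRecord) -> None:
        self._records.append(record)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[QueryRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> QueryRecord:
        return self._records[i]

    def count(
        self,
        endpoint: str | None = None,
        server_id: str | None = None,
        status: str | None = None,
    ) -> int:
        return sum(
            1
            for r in self._records
            if (endpoint is None or r.endpoint == endpoint)
            and (server_id is None or r.server_id == server_id)
            and (status is None or r.status == status)
        )

    def total_epsilon(self) -> float:
        return float(sum(r.epsilon for r in self._records))

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self._records:
                fh.write(
                    json.dumps(
                        {
                            "server_id": r.server_id,
                            "endpoint": r.endpoint,
                            "args": r.args,
                            "epsilon": r.epsilon,
                            "status": r.status,
                        }
                    )
                    + "\n"
                )


def _complete_cases(*vectors: np.ndarray) -> tuple[np.ndarray, ...]:
    """Listwise-complete view of the given equally long vectors."""
    mask = np.ones(vectors[0].shape[0], dtype=bool)
    for v in vectors:
        mask &= np.isfinite(v)
    return tuple(v[mask] for v in vectors)


class Federation:
    """A set of servers behind shared disclosure, noise and budget rules.

    All client-visible behaviour goes through the four endpoint methods;
    the attack modules never touch ``ServerDataset.data`` directly except
    to score a reconstruction against ground truth.
    """

    def __init__(
        self,
        servers: Sequence[ServerDataset],
        policy: DisclosurePolicy | None = None,
        noise: NoisePolicy | None = None,
        accountant: "PrivacyAccountant | None" = None,
        log: QueryLog | None = None,
    ) -> None:
        self.servers: dict[str, ServerDataset] = {s.server_id: s for s in servers}
        if len(self.servers) != len(servers):
            raise ValueError("duplicate server_id")
        self.policy = policy if policy is not None else DisclosurePolicy()
        self.noise = noise if noise is not None else NoisePolicy()
        self.accountant = accountant
        self.log = log if log is not None else QueryLog()
        self._noise_rng = np.random.default_rng(self.noise.rng_seed)

    # -- plumbing ---------------------------------------------------------

    @property
    def server_ids(self) -> list[str]:
        return list(self.servers)

    def server(self, server_id: str) -> ServerDataset:
        try:
            return self.servers[server_id]
        except KeyError:
            raise UnknownVariable(f"no server {server_id!r}") from None

    def reseed_noise(self, seed: int) -> None:
        """Restart the server-side noise stream (reproducible experiments)."""
        self._noise_rng = np.random.default_rng(seed)

    def with_noise(self, noise: NoisePolicy) -> "Federation":
        """A sibling federation over the same servers, log and accountant
        but a different noise policy (fresh noise stream from its seed)."""
        return Federation(
            list(self.servers.values()),
            policy=self.policy,
            noise=noise,
            accountant=self.accountant,
            log=self.log,
        )

    def complete_case_view(self, server_id: str, variables: Iterable[str]) -> "Federation":
        """Federation exposing only the complete cases of ``variables`` on
        ``server_id`` — the standard pre-processing step before an attack
        on data with missing cells.  Shares the query log and accountant."""
        view = self.server(server_id).complete_case_view(variables)
        return Federation(
            [view],
            policy=self.policy,
            noise=self.noise,
            accountant=self.accountant,
            log=self.log,
        )

    def _clip(self, vec: np.ndarray, ref: str, is_broadcast: bool) -> np.ndarray:
        if self.accountant is None or is_broadcast:
            return vec
        bounds = self.accountant.bounds_for(ref)
        return np.clip(vec, bounds[0], bounds[1])

    # -- endpoints --------------------------------------------------------

    def query_mean(self, server_id: str, ref: str) -> float:
        """Release the sample mean of one server-side vector (T1)."""
        server = self.server(server_id)
        vec, is_bc = server.resolve(ref)
        (vec,) = _complete_cases(vec)
        try:
            self.policy.check_mean(vec)
        except DisclosureRefused:
            self.log.append(QueryRecord(server_id, "mean", ref, status="refused"))
            raise
        eps = 0.0
        value = float(np.mean(vec))
        if self.accountant is not None and not is_bc:
            vec = self._clip(vec, ref, is_bc)
            value = float(np.mean(vec))
            eps = self.accountant.charge_mean(ref, vec.size, self.noise.mean_scale)
            value += self.noise.draw(self._noise_rng, self.noise.mean_noise_sd)
        elif self.accountant is None:
            value += self.noise.draw(self._noise_rng, self.noise.mean_noise_sd)
        self.log.append(QueryRecord(server_id, "mean", ref, eps))
        return value

    def query_cov(self, server_id: str, ref_a: str, ref_b: str) -> float:
        """Release the sample covariance (denominator ``n - 1``) of two
        server-side vectors (T2)."""
        server = self.server(server_id)
        vec_a, bc_a = server.resolve(ref_a)
        vec_b, bc_b = server.resolve(ref_b)
        if vec_a.shape[0] != vec_b.shape[0]:
            raise LengthMismatch(
                f"{ref_a} has length {vec_a.shape[0]} but {ref_b} has {vec_b.shape[0]}"
            )
        vec_a, vec_b = _complete_cases(vec_a, vec_b)
        try:
            self.policy.check_cov(vec_a)
            self.policy.check_cov(vec_b)
            if vec_a.size < 2:
                raise DisclosureRefused("covariance needs at least two complete cases")
        except DisclosureRefused:
            self.log.append(
                QueryRecord(server_id, "cov", f"{ref_a},{ref_b}", status="refused")
            )
            raise
        eps = 0.0
        touches_data = not (bc_a and bc_b)
        if self.accountant is not None and touches_data:
            vec_a = self._clip(vec_a, ref_a, bc_a)
            vec_b = self._clip(vec_b, ref_b, bc_b)
            eps = self.accountant.charge_cov(
                ref_a, vec_a, bc_a, ref_b, vec_b, bc_b, self.noise.cov_scale
            )
        value = _sample_cov(vec_a, vec_b)
        if self.accountant is None or touches_data:
            value += self.noise.draw(self._noise_rng, self.noise.cov_noise_sd)
        self.log.append(QueryRecord(server_id, "cov", f"{ref_a},{ref_b}", eps))
        return value

    def broadcast(self, server_id: str, name: str, matrix: np.ndarray) -> str:
        """Ship a client-known matrix to a server (T3).  Its columns become
        addressable as ``name[i]`` in subsequent queries."""
        server = self.server(server_id)
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim == 1:
            matrix = matrix[:, None]
        if matrix.shape[0] != server.n_obs:
            raise ShapeMismatch(
                f"broadcast matrix has {matrix.shape[0]} rows but server "
                f"{server_id!r} holds {server.n_obs} observations"
            )
        server.broadcast_store[name] = matrix.copy()
        self.log.append(
            QueryRecord(server_id, "broadcast", f"{name}:{matrix.shape[0]}x{matrix.shape[1]}")
        )
        return name

    def query_regression_coefficient(
        self, server_id: str, response_ref: str, probe_ref: str
    ) -> float:
        """Release the slope of the simple linear model ``x = y·beta + e``
        fitted server-side with the broadcast probe ``y`` as regressor:
        ``beta_hat = Cov(x, y) / Var(y)``.

        This models platforms that expose linear-model fits rather than a
        covariance endpoint; since the probe (hence ``Var(y)``) is client
        known, the slope is an exact covariance side channel.  Platforms
        of this kind enforce no minimum-count disclosure checks, so none
        are applied here.
        """
        server = self.server(server_id)
        x, bc_x = server.resolve(response_ref)
        y, bc_y = server.resolve(probe_ref)
        if x.shape[0] != y.shape[0]:
            raise LengthMismatch(
                f"{response_ref} has length {x.shape[0]} but {probe_ref} has {y.shape[0]}"
            )
        x, y = _complete_cases(x, y)
        if x.size < 2:
            raise LengthMismatch("regression needs at least two complete cases")
        var_y = _sample_cov(y, y)
        if var_y <= 0.0:
            raise DegenerateProbe(f"probe {probe_ref!r} has zero sample variance")
        eps = 0.0
        cov = _sample_cov(x, y)
        if self.accountant is not None and not bc_x:
            x = self._clip(x, response_ref, bc_x)
            cov = _sample_cov(x, y)
            eps = self.accountant.charge_cov(
                response_ref, x, bc_x, probe_ref, y, bc_y, self.noise.cov_scale
            )
            cov += self.noise.draw(self._noise_rng, self.noise.cov_noise_sd)
        elif self.accountant is None:
            cov += self.noise.draw(self._noise_rng, self.noise.cov_noise_sd)
        self.log.append(
            QueryRecord(server_id, "regression", f"{response_ref}~{probe_ref}", eps)
        )
        return cov / var_y


def _sample_cov(a: np.ndarray, b: np.ndarray) -> float:
    """Two-pass sample covariance with denominator n - 1."""
    n = a.size
    return float((a - a.mean()) @ (b - b.mean()) / (n - 1))


# -- module-level functional surface -------------------------------------
#
# Thin wrappers for callers that hold a bare ServerDataset plus explicit
# policies rather than a Federation.


def _one_shot(
    server: ServerDataset, policy: DisclosurePolicy, noise: NoisePolicy
) -> Federation:
    return Federation([server], policy=policy, noise=noise)


def query_mean(
    server: ServerDataset,
    ref: str,
    policy: DisclosurePolicy | None = None,
    noise: NoisePolicy | None = None,
) -> float:
    fed = _one_shot(server, policy or DisclosurePolicy(), noise or NoisePolicy())
    return fed.query_mean(server.server_id, ref)


def query_cov(
    server: ServerDataset,
    ref_a: str,
    ref_b: str,
    policy: DisclosurePolicy | None = None,
    noise: NoisePolicy | None = None,
) -> float:
    fed = _one_shot(server, policy or DisclosurePolicy(), noise or NoisePolicy())
    return fed.query_cov(server.server_id, ref_a, ref_b)


def broadcast(server: ServerDataset, name: str, matrix: np.ndarray) -> str:
    fed = _one_shot(server, DisclosurePolicy(enabled=False), NoisePolicy())
    return fed.broadcast(server.server_id, name, matrix)


def query_regression_coefficient(
    server: ServerDataset, response_ref: str, probe_ref: str
) -> float:
    fed = _one_shot(server, DisclosurePolicy(enabled=False), NoisePolicy())
    return fed.query_regression_coefficient(server.server_id, response_ref, probe_ref)
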