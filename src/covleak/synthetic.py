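"""Synthetic federations mimicking the structure of the CNSIM tutorial
dataset of the DataSHIELD ecosystem: three data-owning servers holding a
total of 9379 observations of 11 obesity-related variables — a mix of
continuous laboratory/anthropometric measurements (five metric
variables, among them a BMI-like column) and dichotomous indicators
(sex, disease and medication flags).

Only the *structure* is emulated: server count, sample sizes, variable
mix, value ranges, and optional missing-completely-at-random cells.  The
exact marginal distributions of the real CNSIM files are not public, so
the generator documents its own parameter choices.  Every draw flows
from one seed, and the written CSV files are byte-identical across runs
with the same specification.

A loader for real CNSIM CSV exports (produced by the user from the
DSData R package; not redistributed here) is also provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SpecInvalid
from .testbed import ServerDataset, Variable

__all__ = [
    "VariableSpec",
    "FederationSpec",
    "generate_federation",
    "load_cnsim_csv",
    "CNSIM_SERVER_SIZES",
]

#: row counts of the three CNSIM files (total 9379 observations)
CNSIM_SERVER_SIZES = (2163, 3088, 4128)


@dataclass(frozen=True)
class VariableSpec:
    """One column of the generated federation.

    Continuous columns are normal draws (``mean``, ``sd``) optionally
    clipped to ``[low, high]``; dichotomous columns are Bernoulli(``p``)
    in {0, 1}, with both levels forced to occur at least three times
    whenever the sample size permits, so generated data always satisfy
    the minimum-level-count disclosure rule by construction.
    """

    name: str
    kind: str = "continuous"
    mean: float = 0.0
    sd: float = 1.0
    low: float | None = None
    high: float | None = None
    p: float = 0.5


#: default 11-variable panel: 5 metric + 6 dichotomous, BMI-like column
#: at N(27, 4^2) clipped to the physiologically plausible [15, 50]
DEFAULT_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("bmi", "continuous", mean=27.0, sd=4.0, low=15.0, high=50.0),
    VariableSpec("cholesterol_total", "continuous", mean=5.9, sd=1.1, low=2.0, high=12.0),
    VariableSpec("triglycerides", "continuous", mean=1.7, sd=0.9, low=0.2, high=8.0),
    VariableSpec("hdl", "continuous", mean=1.5, sd=0.4, low=0.4, high=3.5),
    VariableSpec("glucose", "continuous", mean=5.4, sd=1.2, low=2.5, high=15.0),
    VariableSpec("female", "dichotomous", p=0.5),
    VariableSpec("diabetes", "dichotomous", p=0.06),
    VariableSpec("stroke", "dichotomous", p=0.04),
    VariableSpec("myocardial_infarction", "dichotomous", p=0.05),
    VariableSpec("lipid_medication", "dichotomous", p=0.12),
    VariableSpec("current_smoker", "dichotomous", p=0.25),
)


@dataclass
class FederationSpec:
    """Shape and distribution of a synthetic federation."""

    n_per_server: Sequence[int] = CNSIM_SERVER_SIZES
    variables: Sequence[VariableSpec] = DEFAULT_VARIABLES
    missingness_rate: float = 0.0
    seed: int = 0

    @property
    def n_servers(self) -> int:
        return len(self.n_per_server)

    def validate(self) -> None:
        if self.n_servers < 1:
            raise SpecInvalid("need at least one server")
        if any(n < 1 for n in self.n_per_server):
            raise SpecInvalid("every server needs at least one observation")
        if not self.variables:
            raise SpecInvalid("need at least one variable")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise SpecInvalid("missingness_rate must lie in [0, 1)")
        for v in self.variables:
            if v.kind not in ("continuous", "dichotomous"):
                raise SpecInvalid(f"unknown kind {v.kind!r} for variable {v.name!r}")
            if v.kind == "continuous" and v.sd <= 0:
                raise SpecInvalid(f"variable {v.name!r} needs sd > 0")
            if v.kind == "dichotomous" and not 0.0 < v.p < 1.0:
                raise SpecInvalid(f"variable {v.name!r} needs 0 < p < 1")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SpecInvalid("duplicate variable names")

    @classmethod
    def from_dict(cls, d: dict) -> "FederationSpec":
        variables = tuple(
            VariableSpec(**v) if isinstance(v, dict) else v
            for v in d.get("variables", DEFAULT_VARIABLES)
        )
        spec = cls(
            n_per_server=tuple(d.get("n_per_server", CNSIM_SERVER_SIZES)),
            variables=variables,
            missingness_rate=float(d.get("missingness_rate", 0.0)),
            seed=int(d.get("seed", 0)),
        )
        spec.validate()
        return spec

    def to_dict(self) -> dict:
        return {
            "n_per_server": list(self.n_per_server),
            "variables": [asdict(v) for v in self.variables],
            "missingness_rate": self.missingness_rate,
            "seed": self.seed,
        }


def _draw_column(spec: VariableSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "continuous":
        x = rng.normal(spec.mean, spec.sd, size=n)
        lo = -np.inf if spec.low is None else spec.low
        hi = np.inf if spec.high is None else spec.high
        return np.clip(x, lo, hi)
    x = (rng.random(n) < spec.p).astype(float)
    # guarantee both levels occur >= 3 times whenever n permits, so the
    # dichotomous disclosure rule is satisfiable by construction
    if n >= 6:
        for level in (0.0, 1.0):
            short = 3 - int(np.sum(x == level))
            if short > 0:
                donors = np.flatnonzero(x != level)
                flip = rng.choice(donors, size=short, replace=False)
                x[flip] = level
    return x


def generate_federation(
    spec: FederationSpec, out_dir: str | Path | None = None
) -> tuple[list[ServerDataset], dict[str, pd.DataFrame]]:
    """Generate the servers of a synthetic federation.

    Returns ``(servers, ground_truth)`` where ``ground_truth`` maps each
    server id to the fully observed data frame *before* missingness was
    injected — the scoring reference for reconstruction experiments.
    When ``out_dir`` is given, one CSV per server, one ground-truth CSV
    per server and a JSON echo of the specification are written there.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    servers: list[ServerDataset] = []
    truth: dict[str, pd.DataFrame] = {}
    for j, (n_j, child) in enumerate(zip(spec.n_per_server, root.spawn(spec.n_servers)), 1):
        rng = np.random.default_rng(child)
        cols = {v.name: _draw_column(v, n_j, rng) for v in spec.variables}
        full = pd.DataFrame(cols)
        observed = full.copy()
        if spec.missingness_rate > 0:
            mask = rng.random(full.shape) < spec.missingness_rate
            observed = observed.mask(mask)
        server_id = f"server{j}"
        meta = [Variable(v.name, v.kind) for v in spec.variables]
        # columns that lost a level to missingness are re-classified
        try:
            servers.append(ServerDataset(server_id, observed, meta))
        except ValueError:
            servers.append(ServerDataset(server_id, observed))
        truth[server_id] = full
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in servers:
            s.data.to_csv(out / f"{s.server_id}.csv", index=False)
            truth[s.server_id].to_csv(out / f"{s.server_id}_truth.csv", index=False)
        (out / "federation_spec.json").write_text(
            json.dumps(spec.to_dict(), indent=2) + "\n"
        )
    return servers, truth


def load_cnsim_csv(
    paths: Sequence[str | Path], complete_case_vars: Sequence[str] = ()
) -> list[ServerDataset]:
    """Load CNSIM-style CSV exports, one file per server.

    Non-numeric columns (e.g. factor labels) are coded as integer level
    codes; empty cells are missing.  When ``complete_case_vars`` is
    given, rows with a missing value in any of those columns are dropped
    (listwise complete-case filtering) and the resulting per-server
    sample sizes are what the endpoints will see.
    """
    servers = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FormatError(f"file not found: {path}")
        df = pd.read_csv(path)
        if df.shape[1] < 1 or df.shape[0] < 1:
            raise FormatError(f"{path} has no data")
        missing = [v for v in complete_case_vars if v not in df.columns]
        if missing:
            raise FormatError(f"{path} lacks expected columns: {missing}")
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                df[col] = df[col].astype("category").cat.codes.replace(-1, np.nan)
        if complete_case_vars:
            df = df.dropna(subset=list(complete_case_vars)).reset_index(drop=True)
        servers.append(ServerDataset(path.stem, df))
    return servers
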