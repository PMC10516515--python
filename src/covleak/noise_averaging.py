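"""Robustness of the attack to zero-mean output perturbation.

If the server adds zero-mean noise ``gamma`` to the released mean and
``eps_i`` to each released covariance, the reconstruction becomes

    x_noisy = x + (n-1) (Y^T)^{-1} eps + n gamma (Y^T)^{-1} m,

i.e. the true data plus a zero-mean disturbance.  Averaging ``R``
independent noisy reconstructions (fresh noise each repetition, probes
held fixed) therefore converges to ``x`` in probability at rate
``sqrt(R)`` — equivalently, the mean squared error of the averaged
estimator falls like ``1/R``.  Output noise alone is no defence against
an analyst with an unbounded query budget.

The experiment driver reproduces the MSE-versus-R sweep at configurable
scale: a grid of noise levels and repetition counts, many replicates,
summarised by the median and the 5th/95th percentiles of the relative
MSE (MSE divided by the sample variance of the true vector).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .attack import ProbeMatrix, ReconstructionResult, generate_probes, reconstruct_variable
from .testbed import Federation, NoisePolicy

__all__ = [
    "NoisyAttackExperiment",
    "attack_noisy_once",
    "averaged_attack",
    "run_noise_experiment",
]


def attack_noisy_once(
    fed: Federation,
    server_id: str,
    variable: str,
    probes: ProbeMatrix,
    noise: NoisePolicy,
    probe_name: str | None = None,
) -> ReconstructionResult:
    """One reconstruction through noise-perturbed endpoints.

    With both noise standard deviations equal to zero this reduces
    bit-for-bit to the noiseless attack.
    """
    noisy_fed = fed.with_noise(noise)
    return reconstruct_variable(
        noisy_fed, server_id, variable, probes=probes, probe_name=probe_name
    )


def averaged_attack(
    fed: Federation,
    server_id: str,
    variable: str,
    probes: ProbeMatrix,
    noise: NoisePolicy,
    R: int,
    seed: int | None = None,
) -> ReconstructionResult:
    """Mean of ``R`` independent noisy reconstructions.

    The probes are broadcast once and held fixed; only the server-side
    noise is redrawn between repetitions (the estimator averages over
    noise, not probes).  ``seed`` restarts the noise stream, making the
    whole averaged run reproducible.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    noisy_fed = fed.with_noise(noise)
    if seed is not None:
        noisy_fed.reseed_noise(seed)
    probe_name = f"_avg_probe_{variable}"
    noisy_fed.broadcast(server_id, probe_name, probes.Y)

    acc: np.ndarray | None = None
    last: ReconstructionResult | None = None
    for _ in range(R):
        last = reconstruct_variable(
            noisy_fed, server_id, variable, probes=probes,
            probe_name=probe_name, score=False,
        )
        acc = last.x_hat if acc is None else acc + last.x_hat
    assert acc is not None and last is not None
    result = ReconstructionResult(
        x_hat=acc / R,
        V_tilde=last.V_tilde,
        m_tilde=last.m_tilde,
        mean_x=last.mean_x,
        target=(server_id, variable),
        channel="cov",
        n_queries=R * (probes.n + 1),
    )
    truth = fed.server(server_id).column(variable)
    if np.all(np.isfinite(truth)):
        result.score(truth)
    return result


@dataclass
class NoisyAttackExperiment:
    """Grid configuration for the MSE-versus-R robustness experiment.

    ``noise_levels`` are *relative* levels: a level ``l`` perturbs both
    the mean and the covariance releases with sd ``l * sd(x)``, where
    ``sd(x)`` is the sample standard deviation of the target variable.
    """

    R_values: Sequence[int] = (1, 10, 100)
    noise_levels: Sequence[float] = (0.01, 0.1, 1.0, 10.0)
    replicates: int = 200
    seed: int = 0
    target_server: str | None = None
    target_variable: str | None = None
    results: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if any(r < 1 for r in self.R_values):
            raise ValueError("all repetition counts must be >= 1")
        if any(l < 0 for l in self.noise_levels):
            raise ValueError("noise levels must be nonnegative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def run_noise_experiment(
    config: NoisyAttackExperiment, fed: Federation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full (noise level, R, replicate) grid.

    Returns ``(results, summary)``: one relative-MSE row per grid cell
    and replicate, and the per-(level, R) median / 5th / 95th percentile
    table.  Probes are drawn fresh per replicate and shared across the
    cells of that replicate, so cells differ only in noise.
    """
    server_id = config.target_server or fed.server_ids[0]
    server = fed.server(server_id)
    variable = config.target_variable
    if variable is None:
        continuous = [v.name for v in server.variables if v.kind == "continuous"]
        variable = continuous[0] if continuous else server.variable_names[0]
    truth = server.column(variable)
    sd_x = float(np.std(truth, ddof=1))

    root = np.random.SeedSequence(config.seed)
    rows = []
    for rep, rep_seq in enumerate(root.spawn(config.replicates)):
        probe_seed = int(rep_seq.generate_state(1, dtype=np.uint32)[0] >> 1)
        probes = generate_probes(server.n_obs, probe_seed)
        for level in config.noise_levels:
            for R in config.R_values:
                noise = NoisePolicy(
                    mean_noise_sd=level * sd_x,
                    cov_noise_sd=level * sd_x,
                    distribution="gaussian",
                )
                res = averaged_attack(
                    fed, server_id, variable, probes, noise, R,
                    seed=probe_seed + 1,
                )
                rows.append(
                    {
                        "noise_level": level,
                        "R": R,
                        "replicate": rep,
                        "relative_mse": res.error_metrics["relative_mse"],
                    }
                )
    results = pd.DataFrame(rows)
    summary = (
        results.groupby(["noise_level", "R"])["relative_mse"]
        .agg(
            median="median",
            p05=lambda s: s.quantile(0.05),
            p95=lambda s: s.quantile(0.95),
        )
        .reset_index()
    )
    config.results = results
    return results, summary
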