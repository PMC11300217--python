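"""Per-environment accuracy metrics, variance decomposition, and the grid runner.

Predictive ability is the Pearson correlation between adjusted phenotypes
and predictions within each environment, alongside the mean squared error;
replicate partitions are aggregated by the arithmetic mean. Correlations
are undefined (carried as missing, never as 0) when either side is
constant -- the characteristic failure of the genotype-independence model
M1 under CV1 partitions. The variance decomposition mirrors the full-data
analysis: the share of each model term across environments and, after
removing the environment main effect, within environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import AllocationDesign, enumerate_grid, sample_partition
from .markers import KinshipMatrix
from .models import MCMCSettings, FitResult, fit_model, predict

__all__ = [
    "EnvMetric",
    "VarianceDecomposition",
    "GridResults",
    "pearson",
    "mse",
    "evaluate_partition",
    "decompose_variance",
    "run_grid",
]

# Spread below this (relative, near machine precision) counts as constant.
_ZERO_SPREAD = 1e-8


def _is_constant(x: np.ndarray) -> bool:
    return float(np.ptp(x)) <= _ZERO_SPREAD * (1.0 + float(np.max(np.abs(x))))


def pearson(observed, predicted) -> float | None:
    """Product-moment correlation; None when either side has no variance."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 2:
        raise ValueError("need at least two pairs")
    if _is_constant(obs) or _is_constant(pred):
        return None
    return float(np.corrcoef(obs, pred)[0, 1])


def mse(observed, predicted) -> float:
    """Mean squared difference."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    return float(np.mean((obs - pred) ** 2))


@dataclass
class EnvMetric:
    env: str
    pearson_r: float | None
    mse: float | None
    n_cells: int


@dataclass
class PartitionEvaluation:
    """Metrics of one fitted partition: per environment plus the means."""

    per_env: list[EnvMetric]
    mean_r: float | None
    mean_mse: float | None
    n_defined_r: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.env, m.pearson_r, m.mse, m.n_cells) for m in self.per_env],
            columns=["env", "pearson_r", "mse", "n_cells"],
        )


def evaluate_partition(
    predictions: pd.DataFrame, environments: list[str]
) -> PartitionEvaluation:
    """Per-environment r and MSE over a prediction table (genotype, env, obs, pred).

    Environments with fewer than two prediction cells, or with a constant
    side, get undefined metrics; across-environment means cover the
    defined ones only, with the count reported.
    """
    metrics = []
    for env in environments:
        sub = predictions.loc[predictions["env"] == env]
        n = len(sub)
        if n < 2:
            metrics.append(EnvMetric(env, None, None, n))
            continue
        obs = sub["obs"].to_numpy()
        pred = sub["pred"].to_numpy()
        metrics.append(EnvMetric(env, pearson(obs, pred), mse(obs, pred), n))
    r_values = [m.pearson_r for m in metrics if m.pearson_r is not None]
    mse_values = [m.mse for m in metrics if m.mse is not None]
    return PartitionEvaluation(
        per_env=metrics,
        mean_r=float(np.mean(r_values)) if r_values else None,
        mean_mse=float(np.mean(mse_values)) if mse_values else None,
        n_defined_r=len(r_values),
    )


@dataclass
class VarianceDecomposition:
    """Percent of variance per term, across and within environments."""

    across: dict[str, float]
    within: dict[str, float]


def decompose_variance(fit: FitResult) -> VarianceDecomposition:
    """Variance-explained percentages from a full-data fit.

    Each term contributes sigma^2_k scaled by the mean diagonal of its
    kernel (the exact variance of a N(0, sigma^2 K) effect; the factor is
    1 for standardized kernels). Within-environment percentages drop the
    environment term and renormalize. Terms absent from the model are
    omitted.
    """
    contrib = {
        name: fit.variance_components[name] * fit.kernel_diag_means[name]
        for name in fit.effects
    }
    contrib["residual"] = fit.variance_components["residual"]
    total = sum(contrib.values())
    across = {k: 100.0 * v / total for k, v in contrib.items()}
    within_terms = {k: v for k, v in contrib.items() if k != "E"}
    wtotal = sum(within_terms.values())
    within = {k: 100.0 * v / wtotal for k, v in within_terms.items()}
    return VarianceDecomposition(across=across, within=within)


@dataclass
class GridResults:
    """Tidy outputs of a full experiment grid run."""

    per_env: pd.DataFrame       # size, design, model, replicate, env, r, mse, n
    per_replicate: pd.DataFrame  # size, design, model, replicate, mean r / mse
    skipped: list[tuple[int, str, str]] = field(default_factory=list)

    def design_means(self) -> pd.DataFrame:
        """Replicate-averaged accuracy per (size, design, model)."""
        return (
            self.per_replicate.groupby(["size", "design", "model"], as_index=False)
            .agg(mean_r=("mean_r", "mean"), mean_mse=("mean_mse", "mean"))
        )


def run_grid(
    phenotypes: pd.DataFrame,
    kinship: KinshipMatrix,
    calibration_sizes: tuple[int, ...] = (186, 168, 144, 120, 96, 72),
    models: tuple[str, ...] = ("M1", "M2", "M3"),
    n_replicates: int = 10,
    prediction_size: int = 930,
    settings: MCMCSettings | None = None,
    base_seed: int = 0,
) -> GridResults:
    """Run the full design x model x replicate experiment.

    For each (calibration size, design) of the enumeration grid and each
    replicate, one partition is sampled (seed = base_seed * 1000 +
    replicate, salted per size/design) and shared by all models so the
    comparison uses a common prediction set. Designs infeasible for the
    genotype count are recorded as skipped.
    """
    genotypes = list(phenotypes.index)
    environments = list(phenotypes.columns)
    T = len(environments)
    settings = settings or MCMCSettings()
    grid = enumerate_grid(len(genotypes), T, tuple(calibration_sizes))
    env_rows = []
    rep_rows = []
    skipped = []
    for grid_pos, (size, design) in enumerate(grid):
        for rep in range(1, n_replicates + 1):
            part_seed = (base_seed * 1000 + rep) + 7919 * grid_pos
            try:
                partition = sample_partition(
                    design, genotypes, environments, prediction_size,
                    seed=part_seed, replicate=rep,
                )
            except ValueError as err:
                skipped.append((size, design.label, str(err)))
                break
            for model in models:
                fit = fit_model(
                    model,
                    phenotypes,
                    kinship,
                    partition.calibration,
                    MCMCSettings(
                        settings.n_iter, settings.burn_in, settings.thin,
                        seed=part_seed + 131 * (1 + list(models).index(model)),
                    ),
                )
                evaluation = evaluate_partition(
                    predict(fit, partition, phenotypes), environments
                )
                for m in evaluation.per_env:
                    env_rows.append(
                        (size, design.label, model, rep, m.env,
                         m.pearson_r, m.mse, m.n_cells)
                    )
                rep_rows.append(
                    (size, design.label, model, rep,
                     evaluation.mean_r, evaluation.mean_mse,
                     evaluation.n_defined_r)
                )
    per_env = pd.DataFrame(
        env_rows,
        columns=["size", "design", "model", "replicate", "env",
                 "pearson_r", "mse", "n_cells"],
    )
    per_replicate = pd.DataFrame(
        rep_rows,
        columns=["size", "design", "model", "replicate",
                 "mean_r", "mean_mse", "n_defined_r"],
    )
    return GridResults(per_env, per_replicate, skipped)
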