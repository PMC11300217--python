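"""Synthetic multi-environment trial data with a controlled variance structure.

Generates the three layers the analysis pipeline consumes:

1. a genotype x marker dosage matrix on the polyploid 0-2 scale
   (:func:`simulate_marker_matrix`),
2. the generative truth -- environment, genotype, genomic, and GxE effects
   with exact in-sample variance fractions (:func:`simulate_true_signals`),
3. plot-level trial records laid out in replicates and incomplete blocks
   with replicated checks (:func:`simulate_plot_data`), plus the cell-level
   adjusted-phenotype grid used by the prediction models
   (:func:`simulate_adjusted_phenotypes`).

Trait presets encode the observed decomposition of sucrose accumulation
(SA, environment ~48% of total variance) and tons of cane per hectare
(TCH, environment ~81%) in a sugarcane diversity panel; total phenotypic
variance is normalised to 1 so component variances equal their fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import MarkerMatrix

__all__ = [
    "TRAIT_PRESETS",
    "SimulationConfig",
    "TrueEffects",
    "LayoutError",
    "simulate_marker_matrix",
    "simulate_true_signals",
    "simulate_plot_data",
    "simulate_adjusted_phenotypes",
]

# Across-environment variance fractions per trait. The within-environment
# shares (vL, vg, vgE, vR) sum to one and are scaled by (1 - vE).
_SA_WITHIN = {"vL": 0.119, "vg": 0.344, "vgE": 0.295, "vR": 0.242}
_TCH_WITHIN = {"vL": 0.209, "vg": 0.108, "vgE": 0.235, "vR": 0.448}


def _across(vE: float, within: dict[str, float]) -> dict[str, float]:
    out = {"vE": vE}
    out.update({k: v * (1.0 - vE) for k, v in within.items()})
    return out


TRAIT_PRESETS: dict[str, dict[str, float]] = {
    "SA-like": _across(0.477, _SA_WITHIN),
    "TCH-like": _across(0.807, _TCH_WITHIN),
}

_COMPONENTS = ("vE", "vL", "vg", "vgE", "vR")


class LayoutError(ValueError):
    """The field layout cannot accommodate the requested genotypes."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic trial.

    Defaults mirror the study conditions: 186 genotypes in 6 environments
    (three locations x two years; the third location ran 2 replicates
    instead of 3), dosages in steps of 0.2, three replicated checks per
    incomplete block.
    """

    n_genotypes: int = 186
    n_environments: int = 6
    n_markers: int = 2000
    n_checks: int = 3
    reps_per_env: list[int] = field(default_factory=lambda: [3, 3, 3, 3, 2, 2])
    blocks_per_rep: int = 31
    plots_per_block: int = 9
    dosage_step: float = 0.2
    missing_rate: float = 0.0
    n_families: int = 31
    fst: float = 0.15
    trait_preset: str = "SA-like"
    variance_fractions: dict[str, float] | None = None
    mu: float = 0.0
    check_sd: float = 0.5
    rep_sd: float = 0.25
    block_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 2 or self.n_markers < 1 or self.n_environments < 1:
            raise ValueError(
                "n_genotypes >= 2, n_markers >= 1 and n_environments >= 1 required"
            )
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        n_steps = 2.0 / self.dosage_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("dosage_step must divide 2 exactly")
        if len(self.reps_per_env) != self.n_environments:
            raise ValueError("reps_per_env must have one entry per environment")
        if self.n_families < 1 or not 0.0 <= self.fst < 1.0:
            raise ValueError("n_families >= 1 and fst in [0, 1) required")
        if self.variance_fractions is None:
            if self.trait_preset not in TRAIT_PRESETS:
                raise ValueError(
                    f"unknown trait preset {self.trait_preset!r}; "
                    f"choose from {sorted(TRAIT_PRESETS)} or give variance_fractions"
                )
            self.variance_fractions = dict(TRAIT_PRESETS[self.trait_preset])
        vf = self.variance_fractions
        if set(vf) != set(_COMPONENTS):
            raise ValueError(f"variance_fractions must have keys {_COMPONENTS}")
        if any(v < 0 for v in vf.values()):
            raise ValueError("variance fractions must be nonnegative")
        if abs(sum(vf.values()) - 1.0) > 1e-9:
            raise ValueError("variance fractions must sum to 1")

    @property
    def genotype_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genotypes + 1)]

    @property
    def environment_ids(self) -> list[str]:
        return [f"E{j}" for j in range(1, self.n_environments + 1)]

    @property
    def check_ids(self) -> list[str]:
        return [f"CHK{c}" for c in range(1, self.n_checks + 1)]


@dataclass
class TrueEffects:
    """Generative truth behind one synthetic trial.

    ``genomic_values`` is exactly ``centered markers @ marker_effects``;
    ``gxe_effects`` rows are independent across environments; each
    component's realized (population) variance equals its target fraction
    of the unit total by construction.
    """

    env_effects: np.ndarray         # (n_environments,)
    genotype_effects: np.ndarray    # (n_genotypes,) non-marker genetic residual
    marker_effects: np.ndarray      # (n_markers,)
    genomic_values: np.ndarray      # (n_genotypes,)
    gxe_effects: np.ndarray         # (n_genotypes, n_environments)
    residual_sd: float

    def total_genetic_value(self, i: int, j: int) -> float:
        """Genetic value of genotype i in environment j (no environment term)."""
        return float(
            self.genotype_effects[i] + self.genomic_values[i] + self.gxe_effects[i, j]
        )


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # child seeds: experiment seed + stage index (1=markers, 2=signals, 3=plots)
    return np.random.default_rng(config.seed + stage)


def simulate_marker_matrix(config: SimulationConfig) -> MarkerMatrix:
    """Draw a genotype x marker dosage matrix on the 0-2 grid.

    Per marker a panel allele frequency p ~ Uniform(0.05, 0.95) is drawn.
    Genotypes belong to ``n_families`` breeding families whose allele
    frequencies drift from p by a Balding-Nichols Beta draw with the
    configured fst, giving the within-family genomic relatedness (~2 fst)
    a diversity panel of breeding germplasm shows; without it every
    genotype is genomically unrelated and marker information cannot
    transfer between individuals. Per genotype a beta-binomial count on
    ``2/dosage_step`` steps is scaled back to [0, 2]; the individual-level
    beta mixing (intraclass correlation 4/9) makes the dosage variance
    match the Hardy-Weinberg value 2p(1-p), so VanRaden kinships built
    from these markers have diagonal means near 1. Missing entries (NaN)
    occur independently at ``missing_rate``.
    """
    rng = _stage_rng(config, 1)
    n_steps = round(2.0 / config.dosage_step)
    p = rng.uniform(0.05, 0.95, size=config.n_markers)
    if config.fst > 0 and config.n_families > 1:
        shape = (1.0 - config.fst) / config.fst
        p_fam = rng.beta(
            shape * p, shape * (1.0 - p), size=(config.n_families, config.n_markers)
        )
    else:
        p_fam = np.broadcast_to(p, (config.n_families, config.n_markers))
    fam_of = np.arange(config.n_genotypes) % config.n_families
    p_base = np.clip(p_fam[fam_of], 1e-6, 1.0 - 1e-6)
    # Beta(a*p, a*(1-p)) with a = 1.25 gives rho = 1/(a+1) = 4/9.
    a = 1.25
    p_ind = rng.beta(a * p_base, a * (1.0 - p_base))
    dosages = rng.binomial(n_steps, p_ind).astype(float) * config.dosage_step
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    marker_ids = [f"M{k:05d}" for k in range(1, config.n_markers + 1)]
    return MarkerMatrix(config.genotype_ids, marker_ids, dosages)


def _center_scale(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale so the population variance equals target exactly."""
    x = x - x.mean()
    v = float(np.mean(x**2))
    if target_var == 0.0:
        return np.zeros_like(x)
    if v == 0.0:
        raise ValueError("degenerate draw: zero variance before rescaling")
    return x * math.sqrt(target_var / v)


def simulate_true_signals(markers: MarkerMatrix, config: SimulationConfig) -> TrueEffects:
    """Draw all generative effects and rescale them to the target fractions.

    Total phenotypic variance is 1, so each component's variance equals its
    fraction. Marker effects start N(0, 1) and are rescaled as one scalar so
    genomic values (centered markers times effects) hit their fraction
    exactly in sample. GxE effects follow the reaction-norm covariance --
    the VanRaden kinship of the supplied markers within each environment,
    independent across environments.
    """
    if np.isnan(markers.dosages).any():
        raise ValueError("marker matrix contains missing values; impute first")
    if markers.n_genotypes != config.n_genotypes:
        raise ValueError(
            f"marker matrix has {markers.n_genotypes} genotypes, "
            f"config expects {config.n_genotypes}"
        )
    rng = _stage_rng(config, 2)
    vf = config.variance_fractions
    if config.n_environments == 1:
        # a single environment's effect is absorbed by the intercept
        env = np.zeros(1)
    else:
        env = _center_scale(rng.standard_normal(config.n_environments), vf["vE"])
    L = _center_scale(rng.standard_normal(config.n_genotypes), vf["vL"])
    beta = rng.standard_normal(markers.n_markers)
    W = markers.dosages - markers.dosages.mean(axis=0, keepdims=True)
    g_raw = W @ beta  # column-centered W => g_raw has exact zero mean
    if vf["vg"] == 0.0:
        beta = np.zeros_like(beta)
        g = np.zeros(config.n_genotypes)
    else:
        v = float(np.mean(g_raw**2))
        if v == 0.0:
            raise ValueError("all markers monomorphic: cannot generate genomic values")
        scale = math.sqrt(vf["vg"] / v)
        beta = beta * scale
        g = W @ beta
    # reaction-norm GxE: kinship-structured within each environment,
    # independent across environments (the Hadamard-kernel covariance)
    if vf["vgE"] == 0.0:
        gxe = np.zeros((config.n_genotypes, config.n_environments))
    else:
        p = markers.dosages.mean(axis=0) / 2.0
        denom = float(np.sum(2.0 * p * (1.0 - p)))
        if denom <= 0.0:
            raise ValueError("all markers monomorphic: cannot structure GxE")
        Wc = markers.dosages - 2.0 * p[None, :]
        K = (Wc @ Wc.T) / denom
        K[np.diag_indices_from(K)] += 1e-6
        C = np.linalg.cholesky(K)
        gxe = C @ rng.standard_normal((config.n_genotypes, config.n_environments))
        gxe = _center_scale(gxe.ravel(), vf["vgE"]).reshape(gxe.shape)
    return TrueEffects(
        env_effects=env,
        genotype_effects=L,
        marker_effects=beta,
        genomic_values=g,
        gxe_effects=gxe,
        residual_sd=math.sqrt(vf["vR"]),
    )


def simulate_adjusted_phenotypes(
    truth: TrueEffects, config: SimulationConfig
) -> pd.DataFrame:
    """Cell-level phenotype grid: mu + E_j + L_i + g_i + gE_ij + eps_ij.

    This is the idealised product of the stage-1 adjustment -- one value per
    genotype-in-environment cell -- and the direct input to the prediction
    models. Returns a genotype x environment DataFrame.
    """
    rng = _stage_rng(config, 4)
    G, T = config.n_genotypes, config.n_environments
    eps = rng.standard_normal((G, T)) * truth.residual_sd
    y = (
        config.mu
        + truth.env_effects[None, :]
        + truth.genotype_effects[:, None]
        + truth.genomic_values[:, None]
        + truth.gxe_effects
        + eps
    )
    return pd.DataFrame(y, index=config.genotype_ids, columns=config.environment_ids)


def _env_layout(
    config: SimulationConfig, env_idx: int, rng: np.random.Generator
) -> list[tuple[int, int, str, bool, str | None]]:
    """Plot assignments for one environment.

    Each replicate holds every test genotype exactly once; each incomplete
    block carries the configured checks plus test plots. Spare test slots
    (block capacity beyond the genotype count) become extra check plots.
    Returns (rep, block, entry id, is_check, check id) tuples.
    """
    test_per_block = config.plots_per_block - config.n_checks
    if test_per_block < 0:
        raise LayoutError(
            f"plots_per_block={config.plots_per_block} cannot hold "
            f"{config.n_checks} checks"
        )
    capacity = config.blocks_per_rep * test_per_block
    if capacity < config.n_genotypes:
        raise LayoutError(
            f"replicate capacity {capacity} test plots "
            f"({config.blocks_per_rep} blocks x {test_per_block}) is short by "
            f"{config.n_genotypes - capacity} for {config.n_genotypes} genotypes"
        )
    genotype_ids = config.genotype_ids
    check_ids = config.check_ids
    rows = []
    for rep in range(1, config.reps_per_env[env_idx] + 1):
        order = list(rng.permutation(config.n_genotypes))
        # spare slots filled with extra (randomly chosen) check plots
        spare = capacity - config.n_genotypes
        slots: list[tuple[str, bool, str | None]] = [
            (genotype_ids[i], False, None) for i in order
        ]
        for s in range(spare):
            cid = check_ids[int(rng.integers(config.n_checks))]
            slots.append((cid, True, cid))
        rng.shuffle(slots)
        pos = 0
        for block in range(1, config.blocks_per_rep + 1):
            for cid in check_ids:
                rows.append((rep, block, cid, True, cid))
            for _ in range(test_per_block):
                entry, is_chk, chk = slots[pos]
                rows.append((rep, block, entry, is_chk, chk))
                pos += 1
    return rows


def simulate_plot_data(truth: TrueEffects, config: SimulationConfig) -> pd.DataFrame:
    """Plot-level records for every environment.

    y_ikl = mu + E_j + check effect (check plots) or L_i + g_i + gE_ij
    (test plots) + r_k + b_l(r) + eps_ikl, with replicate, block and plot
    noise at the configured standard deviations and eps at the truth's
    residual sd. Columns: env, rep, block, genotype, is_check, check_id,
    value.
    """
    if truth.gxe_effects.shape != (config.n_genotypes, config.n_environments):
        raise ValueError("truth dimensions inconsistent with config")
    rng = _stage_rng(config, 3)
    check_effects = dict(
        zip(config.check_ids, rng.standard_normal(config.n_checks) * config.check_sd)
    )
    geno_index = {gid: i for i, gid in enumerate(config.genotype_ids)}
    records = []
    for j, env in enumerate(config.environment_ids):
        layout = _env_layout(config, j, rng)
        n_reps = config.reps_per_env[j]
        rep_eff = rng.standard_normal(n_reps) * config.rep_sd
        block_eff = {
            (k + 1, l + 1): rng.standard_normal() * config.block_sd
            for k in range(n_reps)
            for l in range(config.blocks_per_rep)
        }
        for rep, block, entry, is_chk, chk in layout:
            base = config.mu + truth.env_effects[j] + rep_eff[rep - 1]
            base += block_eff[(rep, block)]
            if is_chk:
                base += check_effects[chk]
            else:
                i = geno_index[entry]
                base += truth.total_genetic_value(i, j)
            base += rng.standard_normal() * truth.residual_sd
            records.append((env, rep, block, entry, is_chk, chk, base))
    return pd.DataFrame(
        records,
        columns=["env", "rep", "block", "genotype", "is_check", "check_id", "value"],
    )
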