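"""Multi-kernel Gaussian mixed models for genotype-in-environment cells.

Three nested GBLUP-type models over the n = |genotypes| x T cell grid:

* M1: y_ij = mu + E_j + L_i + eps  (environment and genotype main effects,
  genotypes independent),
* M2: adds the genomic main effect g_i with covariance Z_L G Z_L' from the
  kinship matrix G,
* M3: adds the reaction-norm GxE term with covariance
  (Z_E Z_E') o (Z_L G Z_L') -- the Hadamard product that confines genomic
  covariance to cell pairs sharing an environment.

Each random term has covariance sigma^2_k K_k. Fitting is by Gibbs
sampling with conjugate updates: every kernel is represented exactly
through a column-space factor K_k = X_k X_k' (incidence matrices and a
Cholesky factor of G), effects alpha_k ~ N(0, sigma^2_k I) live in factor
coordinates, and variances carry scaled-inverse-chi-square priors.
Unobserved cells contribute no likelihood; their predictions come from the
factor representation over the full grid. Cell predictions average the
*conditional means* of each effect block over the retained draws
(Rao-Blackwellised), which removes the Monte-Carlo noise of sampled
effects from the point predictions.

A closed-form BLUP oracle (:func:`blup_oracle`) gives exact predictions at
fixed variance components for verifying the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .designs import Partition
from .markers import KinshipMatrix

__all__ = [
    "MODEL_TERMS",
    "CellIndex",
    "KernelSet",
    "MCMCSettings",
    "FitResult",
    "build_kernels",
    "gibbs_fit",
    "blup_oracle",
    "predict",
    "fit_model",
]

MODEL_TERMS = {"M1": ("E", "L"), "M2": ("E", "L", "g"), "M3": ("E", "L", "g", "gE")}


@dataclass
class CellIndex:
    """Ordered genotype-in-environment cells with incidence matrices."""

    genotypes: list[str]
    environments: list[str]

    def __post_init__(self) -> None:
        G, T = len(self.genotypes), len(self.environments)
        self.cells: list[tuple[str, str]] = [
            (g, e) for g in self.genotypes for e in self.environments
        ]
        self._pos = {c: k for k, c in enumerate(self.cells)}
        self.geno_of = np.repeat(np.arange(G), T)
        self.env_of = np.tile(np.arange(T), G)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def Z_E(self) -> np.ndarray:
        Z = np.zeros((self.n_cells, len(self.environments)))
        Z[np.arange(self.n_cells), self.env_of] = 1.0
        return Z

    def Z_L(self) -> np.ndarray:
        Z = np.zeros((self.n_cells, len(self.genotypes)))
        Z[np.arange(self.n_cells), self.geno_of] = 1.0
        return Z

    def indices_of(self, cells) -> np.ndarray:
        try:
            return np.array([self._pos[c] for c in cells], dtype=int)
        except KeyError as err:
            raise KeyError(f"cell {err.args[0]} outside the model grid") from None


@dataclass
class KernelSet:
    """Named cell-level covariance kernels and their exact factors.

    ``covariances[name]`` is the n x n kernel; ``factors[name]`` is an
    n x r matrix X with XX' equal to it. The residual identity kernel is
    implicit.
    """

    cells: CellIndex
    names: tuple[str, ...]
    covariances: dict[str, np.ndarray]
    factors: dict[str, np.ndarray]


def _psd_cholesky(K: np.ndarray, name: str) -> np.ndarray:
    jitter = 0.0
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise ValueError(f"kernel {name!r} is not positive semidefinite")


def build_kernels(model: str, kinship: KinshipMatrix, cells: CellIndex) -> KernelSet:
    """Kernels of one model over a cell grid.

    M1 uses {E, L}; M2 adds the genomic kernel g; M3 adds the Hadamard
    GxE kernel. Raises if a grid genotype is absent from the kinship.
    """
    if model not in MODEL_TERMS:
        raise ValueError(f"unknown model {model!r}; expected one of {list(MODEL_TERMS)}")
    names = MODEL_TERMS[model]
    same_env = (cells.env_of[:, None] == cells.env_of[None, :]).astype(float)
    same_geno = (cells.geno_of[:, None] == cells.geno_of[None, :]).astype(float)
    covariances = {"E": same_env, "L": same_geno}
    factors = {"E": cells.Z_E(), "L": cells.Z_L()}
    if "g" in names:
        G = kinship.submatrix(cells.genotypes).values
        Kg = G[np.ix_(cells.geno_of, cells.geno_of)]
        Xg = _psd_cholesky(G, "g")[cells.geno_of, :]  # Z_L @ chol(G)
        covariances["g"] = Kg
        factors["g"] = Xg
        if "gE" in names:
            covariances["gE"] = same_env * Kg
            # column block j = diag(Z_E[:, j]) @ Xg  =>  XX' = same_env o Kg
            T = len(cells.environments)
            mask = np.equal.outer(cells.env_of, np.arange(T)).astype(float)
            factors["gE"] = np.hstack([Xg * mask[:, [j]] for j in range(T)])
    return KernelSet(cells, names, covariances, factors)


@dataclass
class MCMCSettings:
    """Gibbs chain settings (defaults: 12,000 draws, 2,000 burn-in, thin 5)."""

    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class FitResult:
    """Posterior summaries of one model fit."""

    model: str
    cells: CellIndex
    mu: float
    effects: dict[str, np.ndarray]          # posterior mean per cell, per term
    variance_components: dict[str, float]   # per term + "residual"
    predictions: np.ndarray                 # mu + sum of effects, all cells
    n_retained: int
    settings: MCMCSettings
    kernel_diag_means: dict[str, float] = None  # mean diag of each kernel


def gibbs_fit(
    y_obs: np.ndarray,
    obs_idx: np.ndarray,
    kernels: KernelSet,
    settings: MCMCSettings,
    fix_variance_components: dict[str, float] | None = None,
    prior_df: float = 5.0,
) -> FitResult:
    """Fit a multi-kernel model by Gibbs sampling on the observed cells.

    Parameters
    ----------
    y_obs, obs_idx
        Observed (calibration) cell values and their row indices in the
        kernel grid.
    fix_variance_components
        Optional map term -> variance (plus ``"residual"``). When given,
        variance updates are skipped and the chain samples effects only.

    The update scheme per iteration: intercept (flat prior), then per
    kernel a joint draw of its factor-space effects from the conjugate
    normal (diagonalised once via an eigendecomposition of X_obs'X_obs),
    then scaled-inverse-chi-square variance draws.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    obs_idx = np.asarray(obs_idx, dtype=int)
    if obs_idx.size < 2:
        raise ValueError("need at least two observed cells")
    if y_obs.shape != obs_idx.shape:
        raise ValueError("y_obs and obs_idx must have matching lengths")
    names = kernels.names
    n_obs = obs_idx.size
    rng = np.random.default_rng(settings.seed)

    # one-time diagonalisation per kernel: A = X[obs], A'A = Q diag(S) Q'
    B: dict[str, np.ndarray] = {}   # A @ Q  (n_obs x r)
    C: dict[str, np.ndarray] = {}   # X @ Q  (n x r)
    S: dict[str, np.ndarray] = {}
    for name in names:
        X = kernels.factors[name]
        A = X[obs_idx]
        s, Q = np.linalg.eigh(A.T @ A)
        S[name] = np.clip(s, 0.0, None)
        B[name] = A @ Q
        C[name] = X @ Q

    vy = float(np.var(y_obs)) or 1.0
    fixed = fix_variance_components is not None
    if fixed:
        missing = [k for k in (*names, "residual") if k not in fix_variance_components]
        if missing:
            raise ValueError(f"fix_variance_components lacks terms: {missing}")
        sigma2 = {k: float(fix_variance_components[k]) for k in names}
        sigma2_e = float(fix_variance_components["residual"])
    else:
        r2_each = 0.5 / len(names)
        sigma2 = {k: vy * r2_each for k in names}
        sigma2_e = vy * 0.5
    # prior mode var(y) * R2_k  =>  S0 = mode * (df0 + 2) / df0
    df0 = prior_df
    S0 = {k: vy * (0.5 / len(names)) * (df0 + 2.0) / df0 for k in names}
    S0_e = vy * 0.5 * (df0 + 2.0) / df0

    mu = float(np.mean(y_obs))
    fitted = {k: np.zeros(n_obs) for k in names}
    resid = y_obs - mu

    n = kernels.cells.n_cells
    acc_mu = 0.0
    acc_effects = {k: np.zeros(n) for k in names}
    acc_var = {k: 0.0 for k in (*names, "residual")}
    n_ret = 0

    for it in range(1, settings.n_iter + 1):
        # intercept, flat prior
        r_mu = resid + mu
        mu = float(np.mean(r_mu) + rng.standard_normal() * np.sqrt(sigma2_e / n_obs))
        resid = r_mu - mu

        retain = it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0
        cond_mean: dict[str, np.ndarray] = {}
        for name in names:
            r_k = resid + fitted[name]
            prec = S[name] / sigma2_e + 1.0 / sigma2[name]
            m = (B[name].T @ r_k) / sigma2_e / prec
            alpha = m + rng.standard_normal(m.size) / np.sqrt(prec)
            fitted[name] = B[name] @ alpha
            resid = r_k - fitted[name]
            if retain:
                cond_mean[name] = m
            if not fixed:
                sigma2[name] = (S0[name] * df0 + alpha @ alpha) / rng.chisquare(
                    df0 + alpha.size
                )
        if not fixed:
            sigma2_e = (S0_e * df0 + resid @ resid) / rng.chisquare(df0 + n_obs)

        if retain:
            n_ret += 1
            acc_mu += mu
            for name in names:
                acc_effects[name] += C[name] @ cond_mean[name]
            for name in names:
                acc_var[name] += sigma2[name]
            acc_var["residual"] += sigma2_e

    mu_mean = acc_mu / n_ret
    effects = {k: v / n_ret for k, v in acc_effects.items()}
    predictions = mu_mean + np.sum(list(effects.values()), axis=0)
    return FitResult(
        model={v: k for k, v in MODEL_TERMS.items()}.get(names, "custom"),
        cells=kernels.cells,
        mu=mu_mean,
        effects=effects,
        variance_components={k: v / n_ret for k, v in acc_var.items()},
        predictions=predictions,
        n_retained=n_ret,
        settings=settings,
        kernel_diag_means={
            k: float(np.mean(np.diag(kernels.covariances[k]))) for k in names
        },
    )


def blup_oracle(
    y_obs: np.ndarray,
    obs_idx: np.ndarray,
    kernels: KernelSet,
    variance_components: dict[str, float],
) -> np.ndarray:
    """Exact BLUP predictions for all cells at fixed variance components.

    V = sum_k sigma2_k K_k[obs, obs] + sigma2_eps I; the intercept is the
    GLS mean and predictions are mu + sum_k sigma2_k K_k[:, obs] V^-1
    (y - mu).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    obs_idx = np.asarray(obs_idx, dtype=int)
    sigma2_e = float(variance_components["residual"])
    if sigma2_e <= 0:
        raise ValueError("residual variance must be positive")
    V = sigma2_e * np.eye(obs_idx.size)
    cross = np.zeros((kernels.cells.n_cells, obs_idx.size))
    for name in kernels.names:
        s2 = float(variance_components[name])
        if s2 < 0:
            raise ValueError(f"variance for term {name!r} must be nonnegative")
        K = kernels.covariances[name]
        V += s2 * K[np.ix_(obs_idx, obs_idx)]
        cross += s2 * K[:, obs_idx]
    try:
        cf = linalg.cho_factor(V)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "V is singular; add a ridge to the kinship or residual variance"
        ) from None
    ones = np.ones(obs_idx.size)
    Vi_y = linalg.cho_solve(cf, y_obs)
    Vi_1 = linalg.cho_solve(cf, ones)
    mu = float(ones @ Vi_y / (ones @ Vi_1))
    return mu + cross @ linalg.cho_solve(cf, y_obs - mu)


def predict(
    fit: FitResult, partition: Partition, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Predictions for a partition's prediction cells.

    ``phenotypes`` is the genotype x environment grid of adjusted values
    supplying the observed side of the comparison. Returns a DataFrame
    with columns genotype, env, obs, pred.
    """
    cells = sorted(partition.prediction)
    idx = fit.cells.indices_of(cells)
    rows = [
        (g, e, float(phenotypes.at[g, e]), float(fit.predictions[k]))
        for (g, e), k in zip(cells, idx)
    ]
    return pd.DataFrame(rows, columns=["genotype", "env", "obs", "pred"])


def fit_model(
    model: str,
    phenotypes: pd.DataFrame,
    kinship: KinshipMatrix,
    calibration_cells,
    settings: MCMCSettings,
    fix_variance_components: dict[str, float] | None = None,
) -> FitResult:
    """Convenience wrapper: build the grid and kernels, then Gibbs-fit.

    ``phenotypes`` is the genotype x environment grid; ``calibration_cells``
    an iterable of (genotype, environment) pairs whose values form the
    training data.
    """
    cells = CellIndex(list(phenotypes.index), list(phenotypes.columns))
    kernels = build_kernels(model, kinship, cells)
    calib = sorted(calibration_cells)
    obs_idx = cells.indices_of(calib)
    y_obs = np.array([phenotypes.at[g, e] for g, e in calib], dtype=float)
    return gibbs_fit(y_obs, obs_idx, kernels, settings, fix_variance_components)
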