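"""Stage-1 per-environment mixed model: genotype BLUPs from plot records.

Within one environment the plot value is modelled as

    y_ikl = mu + Check + L_i + r_k + b_l(r) + eps_ikl

with the intercept and per-check indicators fixed, and genotype (L),
replicate (r) and incomplete block nested in replicate (b) as independent
random effects. Variance components are estimated by REML; the genotype
BLUPs (deviations, no intercept added) are the adjusted phenotypes that
feed the stage-2 prediction models.

The REML likelihood is evaluated in the random-effect coordinate space
(Woodbury identity), so each evaluation costs O(q^3) with q the number of
random-effect levels rather than O(n_plots^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "Stage1VarianceComponents",
    "Stage1ConvergenceError",
    "fit_stage1",
    "blup_table",
]


@dataclass
class Stage1VarianceComponents:
    """Variance components of the stage-1 model (squared trait units)."""

    sigma2_L: float
    sigma2_r: float
    sigma2_b: float
    sigma2_eps: float

    def __post_init__(self) -> None:
        for name in ("sigma2_L", "sigma2_r", "sigma2_b", "sigma2_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma2_L": self.sigma2_L,
            "sigma2_r": self.sigma2_r,
            "sigma2_b": self.sigma2_b,
            "sigma2_eps": self.sigma2_eps,
        }


class Stage1ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the optimiser's trace."""


def _dummies(labels) -> tuple[np.ndarray, list]:
    labels = list(labels)
    levels = sorted(set(labels))
    idx = {lev: k for k, lev in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [idx[v] for v in labels]] = 1.0
    return Z, levels


class _REMLProblem:
    """Precomputed cross-products for the three-factor mixed model."""

    def __init__(self, y, X, Z, block_sizes):
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.block_sizes = block_sizes  # (qL, qr, qb)
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _dvec(self, sL, sr, sb):
        qL, qr, qb = self.block_sizes
        return np.concatenate(
            [np.full(qL, sL), np.full(qr, sr), np.full(qb, sb)]
        )

    def _solve_parts(self, sL, sr, sb, se):
        d = self._dvec(sL, sr, sb)
        sd = np.sqrt(d)
        M = (sd[:, None] * self.ZtZ * sd[None, :]) / se + np.eye(self.q)
        cM = linalg.cho_factor(M, lower=True)
        logdet_V = self.n * np.log(se) + 2.0 * np.sum(np.log(np.diag(cM[0])))

        def vinv_cross(AtB, ZtA, ZtB):
            # A' V^-1 B given A'B, Z'A, Z'B
            t = linalg.cho_solve(cM, sd[:, None] * ZtB)
            return (AtB - (sd[:, None] * ZtA).T @ t / se) / se

        XtViX = vinv_cross(self.XtX, self.ZtX, self.ZtX)
        XtViy = vinv_cross(self.Xty[:, None], self.ZtX, self.Zty[:, None])[:, 0]
        ytViy = vinv_cross(np.array([[self.yty]]), self.Zty[:, None],
                           self.Zty[:, None])[0, 0]
        return d, sd, cM, logdet_V, XtViX, XtViy, ytViy

    def neg2_reml(self, log_s):
        sL, sr, sb, se = np.exp(log_s)
        _, _, _, logdet_V, XtViX, XtViy, ytViy = self._solve_parts(sL, sr, sb, se)
        sign, logdet_X = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(XtViX, XtViy)
        yPy = ytViy - XtViy @ beta
        return logdet_V + logdet_X + yPy

    def blups(self, sL, sr, sb, se):
        d, sd, cM, _, XtViX, XtViy, _ = self._solve_parts(sL, sr, sb, se)
        beta = np.linalg.solve(XtViX, XtViy)
        t = self.Zty - self.ZtX @ beta  # Z'(y - X beta)
        w = (t - self.ZtZ @ (sd * linalg.cho_solve(cM, sd * t)) / se) / se
        return d * w, beta


def fit_stage1(
    plots: pd.DataFrame,
    env: str,
    components: Stage1VarianceComponents | None = None,
) -> tuple[Stage1VarianceComponents, pd.DataFrame]:
    """Fit the stage-1 model for one environment.

    Parameters
    ----------
    plots
        Plot table with columns env, rep, block, genotype, is_check,
        check_id, value (all environments; the requested one is selected).
    env
        Environment identifier to fit.
    components
        If given, variance components are held fixed (no REML) and only
        the BLUPs are computed.

    Returns
    -------
    (Stage1VarianceComponents, DataFrame)
        Estimated (or supplied) components and the BLUP table with columns
        genotype, env, blup, n_plots for the non-check genotypes.
    """
    sub = plots.loc[plots["env"] == env].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no plots for environment {env!r}")
    test = sub.loc[~sub["is_check"].astype(bool)]
    genotypes = sorted(pd.unique(test["genotype"]))
    if len(genotypes) < 2:
        raise ValueError("need at least two non-check genotypes")

    y = sub["value"].to_numpy(float)
    y = y - y.mean()  # intercept absorbs the shift; avoids cancellation in y'y
    n = len(y)

    # fixed effects: intercept + one indicator per observed check
    check_rows = sub["is_check"].astype(bool).to_numpy()
    X_cols = [np.ones(n)]
    check_levels = sorted(pd.unique(sub.loc[check_rows, "check_id"].dropna()))
    for c in check_levels:
        X_cols.append(((sub["check_id"] == c) & check_rows).to_numpy(float))
    X = np.column_stack(X_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "singular fixed-effects design (a check level is confounded "
            "with the intercept or never observed alongside test plots)"
        )

    gidx = {g: k for k, g in enumerate(genotypes)}
    Z_L = np.zeros((n, len(genotypes)))
    for row, (g, is_chk) in enumerate(zip(sub["genotype"], check_rows)):
        if not is_chk:
            Z_L[row, gidx[g]] = 1.0
    Z_r, _ = _dummies(sub["rep"])
    Z_b, _ = _dummies(list(zip(sub["rep"], sub["block"])))
    Z = np.hstack([Z_L, Z_r, Z_b])
    problem = _REMLProblem(y, X, Z, (Z_L.shape[1], Z_r.shape[1], Z_b.shape[1]))

    if components is None:
        vy = float(np.var(y)) or 1.0
        x0 = np.log([vy / 4.0, vy / 8.0, vy / 8.0, vy / 2.0])
        res = optimize.minimize(
            problem.neg2_reml,
            x0,
            method="L-BFGS-B",
            bounds=[(-20.0, 12.0)] * 4,
        )
        if not res.success:
            raise Stage1ConvergenceError(
                f"REML did not converge after {res.nit} iterations: {res.message}"
            )
        sL, sr, sb, se = np.exp(res.x)
        components = Stage1VarianceComponents(sL, sr, sb, se)
    u, _ = problem.blups(
        components.sigma2_L,
        components.sigma2_r,
        components.sigma2_b,
        components.sigma2_eps,
    )
    blup_L = u[: len(genotypes)]
    counts = test["genotype"].value_counts()
    out = pd.DataFrame(
        {
            "genotype": genotypes,
            "env": env,
            "blup": blup_L,
            "n_plots": [int(counts[g]) for g in genotypes],
        }
    )
    return components, out


def blup_table(per_env: list[pd.DataFrame]) -> pd.DataFrame:
    """Assemble per-environment BLUP tables into a genotype x environment grid.

    Missing (genotype, environment) combinations appear as NaN; duplicated
    entries raise.
    """
    stacked = pd.concat(per_env, ignore_index=True)
    dup = stacked.duplicated(subset=["genotype", "env"])
    if dup.any():
        pairs = stacked.loc[dup, ["genotype", "env"]].values[:5].tolist()
        raise ValueError(f"duplicated (genotype, environment) entries: {pairs}")
    grid = stacked.pivot(index="genotype", columns="env", values="blup")
    grid.index.name = None
    grid.columns.name = None
    return grid
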