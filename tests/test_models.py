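"""Kernel construction, the Gibbs sampler, and the closed-form BLUP oracle."""

import numpy as np
import pytest

import sparsemet as sm
from sparsemet.designs import AllocationDesign
from sparsemet.markers import KinshipMatrix
from sparsemet.models import (
    CellIndex,
    KernelSet,
    MCMCSettings,
    blup_oracle,
    build_kernels,
    gibbs_fit,
)


@pytest.fixture
def tiny_kinship():
    G = np.array([[1.0, 0.5, 0.2], [0.5, 1.1, 0.3], [0.2, 0.3, 0.9]])
    return KinshipMatrix(["g1", "g2", "g3"], G)


@pytest.fixture
def tiny_cells():
    return CellIndex(["g1", "g2", "g3"], ["e1", "e2"])


def test_kernels_match_bruteforce(tiny_kinship, tiny_cells):
    kern = build_kernels("M3", tiny_kinship, tiny_cells)
    G = tiny_kinship.values
    cells = tiny_cells.cells
    n = len(cells)
    ZE = np.zeros((n, 2))
    ZL = np.zeros((n, 3))
    for r, (g, e) in enumerate(cells):
        ZE[r, ["e1", "e2"].index(e)] = 1
        ZL[r, ["g1", "g2", "g3"].index(g)] = 1
    expected = {
        "E": ZE @ ZE.T,
        "L": ZL @ ZL.T,
        "g": ZL @ G @ ZL.T,
        "gE": (ZE @ ZE.T) * (ZL @ G @ ZL.T),
    }
    for name, K in expected.items():
        np.testing.assert_allclose(kern.covariances[name], K, atol=1e-12)
        X = kern.factors[name]
        np.testing.assert_allclose(X @ X.T, K, atol=1e-6)


def test_environment_kernel_is_indicator(tiny_kinship, tiny_cells):
    kern = build_kernels("M1", tiny_kinship, tiny_cells)
    KE = kern.covariances["E"]
    for a, (_, ea) in enumerate(tiny_cells.cells):
        for b, (_, eb) in enumerate(tiny_cells.cells):
            assert KE[a, b] == (1.0 if ea == eb else 0.0)
    assert set(np.unique(KE)) <= {0.0, 1.0}


def test_gxe_kernel_zero_across_environments(tiny_kinship, tiny_cells):
    kern = build_kernels("M3", tiny_kinship, tiny_cells)
    KgE = kern.covariances["gE"]
    for a, (_, ea) in enumerate(tiny_cells.cells):
        for b, (_, eb) in enumerate(tiny_cells.cells):
            if ea != eb:
                assert KgE[a, b] == 0.0


def test_model_term_sets(tiny_kinship, tiny_cells):
    assert build_kernels("M1", tiny_kinship, tiny_cells).names == ("E", "L")
    assert build_kernels("M2", tiny_kinship, tiny_cells).names == ("E", "L", "g")
    assert build_kernels("M3", tiny_kinship, tiny_cells).names == (
        "E", "L", "g", "gE"
    )


def test_missing_genotype_named(tiny_kinship):
    cells = CellIndex(["g1", "g9"], ["e1"])
    with pytest.raises(KeyError, match="g9"):
        build_kernels("M2", tiny_kinship, cells)


def test_mcmc_settings_retained_count():
    s = MCMCSettings()
    assert (s.n_iter, s.burn_in, s.thin) == (12_000, 2_000, 5)
    assert s.n_retained == 2_000
    with pytest.raises(ValueError):
        MCMCSettings(n_iter=100, burn_in=100)


def test_intercept_only_posterior_mean():
    rng = np.random.default_rng(0)
    y = rng.standard_normal(50) + 3.0
    cells = CellIndex([f"g{i}" for i in range(50)], ["e1"])
    kern = KernelSet(
        cells, ("L",), {"L": np.eye(50)}, {"L": np.eye(50)}
    )
    fit = gibbs_fit(y, np.arange(50), kern, MCMCSettings(4000, 1000, 2, seed=1))
    assert abs(fit.mu - y.mean()) < 3 * np.sqrt(np.var(y) / 50)


def test_oracle_no_signal_returns_mean(tiny_kinship, tiny_cells):
    kern = build_kernels("M2", tiny_kinship, tiny_cells)
    y = np.array([1.0, 2.0, 3.0, 4.0])
    obs = np.array([0, 1, 2, 3])
    vc = {"E": 0.0, "L": 0.0, "g": 0.0, "residual": 1.0}
    preds = blup_oracle(y, obs, kern, vc)
    np.testing.assert_allclose(preds, np.full(6, y.mean()), atol=1e-10)


def test_oracle_identity_kernel_is_ridge_shrinkage():
    n = 8
    cells = CellIndex([f"g{i}" for i in range(n)], ["e1"])
    kern = KernelSet(cells, ("L",), {"L": np.eye(n)}, {"L": np.eye(n)})
    rng = np.random.default_rng(2)
    y = rng.standard_normal(5)
    obs = np.arange(5)
    s2, se = 0.7, 0.4
    preds = blup_oracle(y, obs, kern, {"L": s2, "residual": se})
    # GLS intercept under (s2+se) I is the plain mean
    mu = y.mean()
    expected_obs = mu + s2 / (s2 + se) * (y - mu)
    np.testing.assert_allclose(preds[:5], expected_obs, atol=1e-10)
    np.testing.assert_allclose(preds[5:], mu, atol=1e-10)


def test_oracle_duplicate_genotype_two_cell_toy():
    cells = CellIndex(["a", "b"], ["e1"])
    K = np.array([[1.0, 1.0], [1.0, 1.0]])
    kern = KernelSet(cells, ("L",), {"L": K}, {"L": np.array([[1.0], [1.0]])})
    y = np.array([2.5])
    preds = blup_oracle(y, np.array([0]), kern, {"L": 0.6, "residual": 0.2})
    # single observation: GLS mean equals it; duplicate row gives equal preds
    # hand 2x2 algebra: pred_b = mu + s2*K[b,a]/(s2*K[a,a]+se) * (y - mu)
    assert preds[0] == pytest.approx(2.5, abs=1e-12)
    assert preds[1] == pytest.approx(preds[0], abs=1e-12)


@pytest.fixture(scope="module")
def toy_problem():
    """36-cell grid with data from the generative model."""
    cfg = sm.SimulationConfig(n_genotypes=6, n_markers=200, n_families=3,
                              reps_per_env=[1] * 6, blocks_per_rep=3,
                              plots_per_block=5, seed=5)
    mk = sm.simulate_marker_matrix(cfg)
    K = sm.vanraden_grm(mk)
    truth = sm.simulate_true_signals(mk, cfg)
    y_all = sm.simulate_adjusted_phenotypes(truth, cfg).values.ravel()
    cells = CellIndex(cfg.genotype_ids, cfg.environment_ids)
    kern = build_kernels("M3", K, cells)
    rng = np.random.default_rng(0)
    obs = np.sort(rng.choice(36, size=24, replace=False))
    vc = {"E": 0.4, "L": 0.1, "g": 0.2, "gE": 0.15, "residual": 0.13}
    return y_all, obs, kern, vc


def test_sampler_converges_to_oracle(toy_problem):
    """RMS against the closed form decreases with chain length."""
    y_all, obs, kern, vc = toy_problem
    oracle = blup_oracle(y_all[obs], obs, kern, vc)
    rms = {}
    for n_iter in (2_000, 20_000):
        fit = gibbs_fit(y_all[obs], obs, kern,
                        MCMCSettings(n_iter, n_iter // 10, 5, seed=4),
                        fix_variance_components=vc)
        rms[n_iter] = float(np.sqrt(np.mean((fit.predictions - oracle) ** 2)))
    assert rms[20_000] < rms[2_000]
    assert rms[20_000] < 0.02


def test_sampler_exchangeable_under_cell_permutation(toy_problem):
    y_all, obs, kern, vc = toy_problem
    perm = np.random.default_rng(9).permutation(36)
    inv = np.argsort(perm)
    cells_p = kern.cells  # labels unchanged; permute matrices directly
    kern_p = KernelSet(
        cells_p,
        kern.names,
        {k: v[np.ix_(perm, perm)] for k, v in kern.covariances.items()},
        {k: v[perm] for k, v in kern.factors.items()},
    )
    obs_set = set(obs.tolist())
    obs_p = np.sort([int(np.where(perm == i)[0][0]) for i in obs_set])
    y_p = y_all[perm][obs_p]
    fit = gibbs_fit(y_all[obs], obs, kern,
                    MCMCSettings(20_000, 2_000, 5, seed=4),
                    fix_variance_components=vc)
    fit_p = gibbs_fit(y_p, obs_p, kern_p,
                      MCMCSettings(20_000, 2_000, 5, seed=4),
                      fix_variance_components=vc)
    np.testing.assert_allclose(fit_p.predictions[inv], fit.predictions,
                               atol=0.03)


def test_m1_cv1_predictions_constant_within_environment(small_grid,
                                                        small_kinship):
    genos, envs = list(small_grid.index), list(small_grid.columns)
    part = sm.sample_partition(AllocationDesign(0, 10, 6), genos, envs,
                               prediction_size=280, seed=2)
    vc = {"E": 0.48, "L": 0.06, "residual": 0.46}
    fit = sm.fit_model("M1", small_grid, small_kinship, part.calibration,
                       MCMCSettings(4000, 1000, 5, seed=3),
                       fix_variance_components=vc)
    preds = sm.predict(fit, part, small_grid)
    phen_var = float(np.var(small_grid.values))
    for env in envs:
        v = preds.loc[preds["env"] == env, "pred"].to_numpy()
        assert np.var(v) < 1e-6 * phen_var


def test_predict_row_counts(small_grid, small_kinship):
    genos, envs = list(small_grid.index), list(small_grid.columns)
    part = sm.sample_partition(AllocationDesign(10, 0, 6), genos, envs,
                               prediction_size=300, seed=4)
    fit = sm.fit_model("M2", small_grid, small_kinship, part.calibration,
                       MCMCSettings(1500, 500, 5, seed=1))
    preds = sm.predict(fit, part, small_grid)
    assert len(preds) == 300
    assert set(zip(preds["genotype"], preds["env"])) == part.prediction
    # prediction cells are exactly the complement of calibration here
    full = {(g, e) for g in genos for e in envs}
    assert part.prediction == full - part.calibration
    # empty prediction set gives an empty table
    part.prediction = set()
    assert len(sm.predict(fit, part, small_grid)) == 0


def test_fit_decomposes_predictions(small_grid, small_kinship):
    cells = [(g, e) for g in small_grid.index for e in small_grid.columns]
    fit = sm.fit_model("M2", small_grid, small_kinship, cells,
                       MCMCSettings(1500, 500, 5, seed=6))
    recomposed = fit.mu + sum(fit.effects.values())
    np.testing.assert_allclose(fit.predictions, recomposed, atol=1e-10)
    assert all(v > 0 for v in fit.variance_components.values())
    assert fit.n_retained == (1500 - 500) // 5


def test_gibbs_rejects_bad_inputs(tiny_kinship, tiny_cells):
    kern = build_kernels("M1", tiny_kinship, tiny_cells)
    with pytest.raises(ValueError, match="observed"):
        gibbs_fit(np.array([1.0]), np.array([0]), kern, MCMCSettings(100, 10, 1))
    with pytest.raises(ValueError, match="lacks"):
        gibbs_fit(np.array([1.0, 2.0]), np.array([0, 1]), kern,
                  MCMCSettings(100, 10, 1),
                  fix_variance_components={"E": 1.0, "residual": 1.0})
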