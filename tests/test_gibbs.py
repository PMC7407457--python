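"""The multi-kernel Gibbs sampler: oracle equivalence and invariances."""

import numpy as np
import pytest
from sklearn.base import clone

import sparsegp as sp
from sparsegp.gibbs import GibbsKernelRegressor, effective_sample_size


@pytest.fixture(scope="module")
def toy():
    """20 genotypes x 2 environments with a moderately structured GRM."""
    ds = sp.simulate_dataset(
        sp.SimulationConfig(n_genotypes=20, n_markers=40, n_envs=2, seed=11),
        with_plots=False,
    )
    blues = ds.cell_values.rename(columns={"value": "blue"})
    design = sp.make_design(list(ds.markers.genotype_ids), 2, 6, 4, seed=2)
    return ds, blues, design


FIXED = {"E": 0.5, "L": 0.1, "G": 0.3, "GE": 0.5, "residual": 0.4}


def henderson_predictions(ds, blues, design, fixed):
    """Dense joint-Gaussian BLUP with known variances (independent oracle)."""
    import pandas as pd

    cells, kernels = sp.build_kernels(ds.grm, design, "M3")
    cal = np.array(
        [(e, g) in design.calibration_cells for e, g in zip(cells["env"], cells["genotype"])]
    )
    idx = np.nonzero(cal)[0]
    y = (
        blues.set_index(["env", "genotype"])["blue"]
        .reindex(pd.MultiIndex.from_frame(cells[["env", "genotype"]]))
        .to_numpy()
    )
    C = sum(fixed[lab] * K for lab, K in kernels.items())
    V = C[np.ix_(idx, idx)] + fixed["residual"] * np.eye(len(idx))
    Vi = np.linalg.inv(V)
    one = np.ones(len(idx))
    mu = (one @ Vi @ y[idx]) / (one @ Vi @ one)
    return mu + C[:, idx] @ Vi @ (y[idx] - mu)


class TestOracleEquivalence:
    def test_fixed_variance_gibbs_matches_henderson_blup(self, toy):
        """With variances fixed at truth the posterior-mean predictions must
        agree with the closed-form mixed-model (Henderson) solution within
        Monte-Carlo error.  Three independent chains are pooled, standard
        practice for validating an MCMC implementation against an oracle."""
        ds, blues, design = toy
        oracle = henderson_predictions(ds, blues, design, FIXED)
        pooled, ess_total = [], 0.0
        for seed in (0, 1, 2):
            fit = sp.fit_model(
                blues, ds.grm, design, "M3",
                sp.GibbsConfig(n_iter=8000, burn_in=1500, thin=2, seed=seed),
                fixed_varcomps=FIXED,
            )
            pooled.append(fit.estimator.predict_samples(np.arange(len(oracle))))
        samples = np.vstack(pooled)
        ess = np.array(
            [
                sum(effective_sample_size(chain[:, i]) for chain in pooled)
                for i in range(samples.shape[1])
            ]
        )
        mc_se = samples.std(axis=0, ddof=1) / np.sqrt(ess)
        z = np.abs(samples.mean(axis=0) - oracle) / mc_se
        assert z.max() < 3.0


class TestSamplerBehaviour:
    def test_constant_response_recovers_constant(self):
        K = np.eye(12)
        est = GibbsKernelRegressor(
            kernels={"U": K}, n_iter=1500, burn_in=300, random_state=0
        )
        y = np.full(12, 4.0)
        est.fit(np.arange(12), y)
        assert est.mu_ == pytest.approx(4.0, abs=0.05 * 4.0)
        assert np.all(np.abs(est.predict(np.arange(12)) - 4.0) <= 0.05 * 4.0)

    def test_scale_equivariance(self, toy):
        """Scaling y by c scales variances by c^2 and predictions by c."""
        ds, blues, design = toy
        cfg = sp.GibbsConfig(n_iter=4000, burn_in=1000, seed=13)
        f1 = sp.fit_model(blues, ds.grm, design, "M2", cfg)
        c = 3.0
        scaled = blues.assign(blue=blues["blue"] * c)
        f2 = sp.fit_model(scaled, ds.grm, design, "M2", cfg)
        for lab, v in f1.varcomps.items():
            assert f2.varcomps[lab] == pytest.approx(c**2 * v, rel=0.30)
        p1 = f1.cell_predictions["predicted"].to_numpy()
        p2 = f2.cell_predictions["predicted"].to_numpy()
        np.testing.assert_allclose(p2, c * p1, atol=0.3 * np.std(c * p1))

    def test_m3_with_zero_interaction_variance_collapses_to_m2(self, toy):
        """Forcing var_gE = 0 makes M3's predictive rule identical to M2's."""
        ds, blues, design = toy
        fixed2 = {"E": 0.5, "L": 0.1, "G": 0.3, "residual": 0.4}
        fixed3 = dict(fixed2, GE=0.0)
        cfg = sp.GibbsConfig(n_iter=6000, burn_in=1000, seed=3)
        f2 = sp.fit_model(blues, ds.grm, design, "M2", cfg, fixed_varcomps=fixed2)
        f3 = sp.fit_model(blues, ds.grm, design, "M3", cfg, fixed_varcomps=fixed3)
        p2 = f2.cell_predictions["predicted"].to_numpy()
        p3 = f3.cell_predictions["predicted"].to_numpy()
        np.testing.assert_allclose(p3, p2, atol=0.05)

    def test_reproducible_given_seed(self, toy):
        ds, blues, design = toy
        cfg = sp.GibbsConfig(n_iter=800, burn_in=200, seed=5)
        f1 = sp.fit_model(blues, ds.grm, design, "M1", cfg)
        f2 = sp.fit_model(blues, ds.grm, design, "M1", cfg)
        assert f1.varcomps == f2.varcomps
        np.testing.assert_array_equal(
            f1.cell_predictions["predicted"], f2.cell_predictions["predicted"]
        )


class TestSklearnCompat:
    def test_get_set_params_and_clone(self):
        est = GibbsKernelRegressor(kernels={"U": np.eye(4)}, n_iter=100, burn_in=10)
        params = est.get_params()
        assert params["n_iter"] == 100
        est2 = clone(est)
        assert est2.get_params()["burn_in"] == 10
        est2.set_params(thin=2)
        assert est2.thin == 2

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="kernels"):
            GibbsKernelRegressor(kernels=None).fit(np.arange(3), np.zeros(3))
        with pytest.raises(ValueError, match="burn_in"):
            GibbsKernelRegressor(
                kernels={"U": np.eye(3)}, n_iter=10, burn_in=10
            ).fit(np.arange(3), np.zeros(3))
        with pytest.raises(ValueError, match="calibration cells"):
            GibbsKernelRegressor(kernels={"U": np.eye(3)}).fit([0], [1.0])


def test_effective_sample_size_white_noise():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(2000)
    ess = effective_sample_size(x)
    assert 1000 < ess <= 2100
    # strongly autocorrelated chain has far lower ESS
    y = np.cumsum(rng.standard_normal(2000))
    assert effective_sample_size(y) < 100
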