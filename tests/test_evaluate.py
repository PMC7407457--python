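"""Cross-validation bookkeeping, per-environment scoring and summaries."""

import numpy as np
import pandas as pd
import pytest

import sparsegp as sp
from sparsegp.designs import DesignGrid
from sparsegp.evaluate import CVResult, pearson_by_env, run_cv, summarize, summary_grid

TINY_CFG = sp.GibbsConfig(n_iter=300, burn_in=100, thin=2, seed=0)


def frame(env, genos, values, col):
    return pd.DataFrame({"env": env, "genotype": genos, col: values})


class TestPearsonByEnv:
    def cells(self, genos, env="E1"):
        return {(env, g) for g in genos}

    def test_perfect_and_antiperfect(self):
        genos = list("abcd")
        obs = frame("E1", genos, [1.0, 2.0, 3.0, 4.0], "blue")
        for sign, expect in ((1.0, 1.0), (-1.0, -1.0)):
            pred = frame("E1", genos, sign * np.array([1.0, 2.0, 3.0, 4.0]), "predicted")
            assert pearson_by_env(obs, pred, self.cells(genos), "E1") == pytest.approx(expect)

    def test_hand_computed_correlation(self):
        genos = list("abcd")
        obs = frame("E1", genos, [1.0, 2.0, 3.0, 4.0], "blue")
        pred = frame("E1", genos, [1.0, 3.0, 2.0, 4.0], "predicted")
        assert pearson_by_env(obs, pred, self.cells(genos), "E1") == pytest.approx(0.8)

    def test_constant_vector_warns_and_returns_nan(self):
        genos = list("abcd")
        obs = frame("E1", genos, [1.0, 2.0, 3.0, 4.0], "blue")
        pred = frame("E1", genos, [2.0, 2.0, 2.0, 2.0], "predicted")
        with pytest.warns(UserWarning, match="zero variance"):
            r = pearson_by_env(obs, pred, self.cells(genos), "E1")
        assert np.isnan(r)

    def test_too_few_cells_rejected(self):
        obs = frame("E1", ["a", "b"], [1.0, 2.0], "blue")
        pred = frame("E1", ["a", "b"], [1.0, 2.0], "predicted")
        with pytest.raises(ValueError, match=">= 3"):
            pearson_by_env(obs, pred, {("E1", "a"), ("E1", "b")}, "E1")


@pytest.fixture(scope="module")
def tiny():
    ds = sp.simulate_dataset(
        sp.SimulationConfig(n_genotypes=30, n_markers=80, seed=7), with_plots=False
    )
    return ds, ds.cell_values.rename(columns={"value": "blue"})


class TestRunCv:
    def test_record_counting_contract(self, tiny):
        ds, blues = tiny
        grid = DesignGrid(rows=((8, ((8, 0), (5, 3), (2, 6))),))
        res = run_cv(blues, ds.grm, grid, models=("M1", "M2", "M3"),
                     n_reps=2, base_seed=1, config=TINY_CFG)
        # 2 reps x 3 designs x 3 models x 3 envs
        assert len(res.records) == 54
        assert set(res.records["model"]) == {"M1", "M2", "M3"}

    def test_default_repetition_count_is_25(self):
        import inspect

        assert inspect.signature(run_cv).parameters["n_reps"].default == 25

    def test_reproducible_from_base_seed(self, tiny):
        ds, blues = tiny
        grid = DesignGrid(rows=((6, ((6, 0),)),))
        a = run_cv(blues, ds.grm, grid, models=("M1",), n_reps=2, base_seed=3,
                   config=TINY_CFG)
        b = run_cv(blues, ds.grm, grid, models=("M1",), n_reps=2, base_seed=3,
                   config=TINY_CFG)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_incomplete_factorial_rejected(self, tiny):
        ds, blues = tiny
        grid = DesignGrid(rows=((6, ((6, 0),)),))
        with pytest.raises(ValueError, match="full"):
            run_cv(blues.iloc[:-1], ds.grm, grid, models=("M1",), n_reps=1,
                   base_seed=0, config=TINY_CFG)


class TestSampleSizeDegradation:
    def test_smaller_calibration_sets_do_not_predict_better(self, tiny):
        """Shrinking the per-environment sample size at all-non-overlapping
        composition must not increase mean accuracy (within two Monte-Carlo
        standard deviations of the repetition means)."""
        ds, blues = tiny
        grid = DesignGrid(rows=((10, ((10, 0),)), (4, ((4, 0),))))
        res = run_cv(blues, ds.grm, grid, models=("M2",), n_reps=4, base_seed=2,
                     config=sp.GibbsConfig(n_iter=800, burn_in=200, seed=0))
        s = summarize(res).set_index("sample_size")
        slack = 2 * s["sd_r"].max() / np.sqrt(4)
        assert s.loc[4, "mean_r"] <= s.loc[10, "mean_r"] + slack


class TestSummarize:
    def rec(self, **kw):
        base = dict(rep=0, sample_size=10, NO=10, O=0, model="M1", env="E1",
                    pearson_r=0.5, pct_unexplained=20.0)
        base.update(kw)
        return base

    def test_singleton(self):
        res = CVResult(pd.DataFrame([self.rec()]), n_reps=1, base_seed=0)
        out = summarize(res)
        assert out.loc[0, "mean_r"] == pytest.approx(0.5)
        assert out.loc[0, "sd_r"] == 0.0

    def test_two_reps_hand_arithmetic(self):
        rows = [self.rec(rep=0, pearson_r=0.4), self.rec(rep=1, pearson_r=0.6)]
        out = summarize(CVResult(pd.DataFrame(rows), n_reps=2, base_seed=0))
        assert out.loc[0, "mean_r"] == pytest.approx(0.5)
        assert out.loc[0, "sd_r"] == pytest.approx(0.14142, abs=1e-4)

    def test_environment_averaging_precedes_rep_averaging(self):
        rows = [
            self.rec(rep=0, env="E1", pearson_r=0.2),
            self.rec(rep=0, env="E2", pearson_r=0.4),
            self.rec(rep=1, env="E1", pearson_r=0.8),
            self.rec(rep=1, env="E2", pearson_r=0.6),
        ]
        out = summarize(CVResult(pd.DataFrame(rows), n_reps=2, base_seed=0))
        assert out.loc[0, "mean_r"] == pytest.approx(0.5)
        assert out.loc[0, "sd_r"] == pytest.approx(np.std([0.3, 0.7], ddof=1))

    def test_missing_correlations_excluded_and_counted(self):
        rows = [
            self.rec(rep=0, env="E1", pearson_r=np.nan),
            self.rec(rep=0, env="E2", pearson_r=0.4),
        ]
        out = summarize(CVResult(pd.DataFrame(rows), n_reps=1, base_seed=0))
        assert out.loc[0, "mean_r"] == pytest.approx(0.4)
        assert out.loc[0, "n_missing_r"] == 1

    def test_grid_layout_pivot(self):
        rows = [self.rec(NO=10, O=0), self.rec(NO=7, O=3)]
        out = summarize(CVResult(pd.DataFrame(rows), n_reps=1, base_seed=0))
        g = summary_grid(out)
        assert list(g.columns) == ["10/0", "7/3"]
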