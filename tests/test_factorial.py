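"""Factorial models, marginal means, contrasts and the artifact logit."""

import numpy as np
import pandas as pd
import pytest

import eegmultiverse as emv
from eegmultiverse.factorial import (
    FactorialModelSpec,
    paths_to_frame,
)


def _grid(**steps):
    return {k: list(v) for k, v in steps.items()}


def _responses(grid, fn):
    """Series of responses over the full factorial, built from level dicts."""
    paths = emv.enumerate_paths(grid)
    return pd.Series({p.id: fn(p.as_dict()) for p in paths})


class TestFactorialLM:
    def test_zero_noise_additive_construction_exact(self):
        grid = _grid(a=["0", "1"], b=["x", "y", "z"])
        eff_b = {"x": 0.0, "y": 1.5, "z": -2.0}
        y = _responses(grid, lambda lv: 10.0 + 3.0 * (lv["a"] == "1")
                       + eff_b[lv["b"]])
        m = emv.fit_factorial_lm(y, grid, FactorialModelSpec(response="y"))
        assert m.rsquared == pytest.approx(1.0)
        params = m.params
        assert params["Intercept"] == pytest.approx(10.0)
        assert params["C(a, Treatment('0'))[T.1]"] == pytest.approx(3.0)

    def test_coefficients_recovered_within_cis(self):
        """Known additive effects + N(0, 1) noise: 95% CIs cover truth."""
        rng = np.random.default_rng(0)
        grid = _grid(a=["0", "1"], b=["x", "y"], c=["p", "q", "r"])
        truth = {"a": 2.0, "b": -1.0, "c_q": 0.5, "c_r": 1.5}
        reps = []
        for _ in range(20):   # replicate factorial for power
            y = _responses(grid, lambda lv: (
                truth["a"] * (lv["a"] == "1") + truth["b"] * (lv["b"] == "y")
                + truth.get("c_" + lv["c"], 0.0)))
            reps.append(y + rng.standard_normal(len(y)))
        stacked = pd.concat(reps)
        m = emv.fit_factorial_lm(stacked, grid,
                                 FactorialModelSpec(response="y",
                                                    interactions=False))
        ci = m.results.conf_int()
        checks = {"C(a, Treatment('0'))[T.1]": truth["a"],
                  "C(b, Treatment('x'))[T.y]": truth["b"],
                  "C(c, Treatment('p'))[T.q]": truth["c_q"],
                  "C(c, Treatment('p'))[T.r]": truth["c_r"]}
        for name, val in checks.items():
            lo, hi = ci.loc[name]
            assert lo < val < hi

    def test_interactions_reduce_aic_on_interacting_data(self):
        rng = np.random.default_rng(1)
        grid = _grid(a=["0", "1"], b=["x", "y"])
        reps = []
        for _ in range(30):
            y = _responses(grid, lambda lv: 2.0 * (lv["a"] == "1")
                           + 1.0 * (lv["b"] == "y")
                           + 3.0 * ((lv["a"] == "1") and (lv["b"] == "y")))
            reps.append(y + 0.5 * rng.standard_normal(len(y)))
        stacked = pd.concat(reps)
        with_int = emv.fit_factorial_lm(
            stacked, grid, FactorialModelSpec(response="y"))
        without = emv.fit_factorial_lm(
            stacked, grid, FactorialModelSpec(response="y",
                                              interactions=False))
        assert with_int.aic < without.aic

    def test_rank_deficiency_names_empty_cells(self):
        grid = _grid(a=["0", "1"], b=["x", "y"])
        y = _responses(grid, lambda lv: 1.0)
        # remove every row pairing a=1 with b=y -> that cell is empty
        y = y[~y.index.str.contains("a=1\\|b=y")]
        with pytest.raises(ValueError, match="empty cells"):
            emv.fit_factorial_lm(y, grid, FactorialModelSpec(response="y"))

    def test_paths_to_frame_levels_ordered(self):
        grid = _grid(a=["0", "1"], b=["x", "y"])
        df = paths_to_frame([p.id for p in emv.enumerate_paths(grid)], grid)
        assert list(df["a"].cat.categories) == ["0", "1"]
        assert df.index.name == "path_id"


class TestFactorialLMM:
    def _per_participant(self, tau, sigma=0.3, n_pp=8, seed=2):
        rng = np.random.default_rng(seed)
        grid = _grid(a=["0", "1"], b=["x", "y"])
        paths = emv.enumerate_paths(grid)
        intercepts = tau * rng.standard_normal(n_pp)
        rows = []
        for pid in range(n_pp):
            for p in paths:
                lv = p.as_dict()
                mu = 1.0 + 2.0 * (lv["a"] == "1") - 1.0 * (lv["b"] == "y")
                rows.append(dict(path_id=p.id, participant=pid,
                                 value=mu + intercepts[pid]
                                 + sigma * rng.standard_normal()))
        return pd.DataFrame(rows), grid

    def test_participant_intercept_sd_recovered(self):
        tau = 1.5
        taus = []
        for seed in range(5):
            df, grid = self._per_participant(tau, n_pp=12, seed=seed)
            m = emv.fit_factorial_lmm(df, grid,
                                      FactorialModelSpec(response="value"))
            taus.append(float(np.sqrt(m.results.cov_re.iloc[0, 0])))
        assert abs(np.mean(taus) - tau) < 0.5

    def test_zero_variance_matches_plain_lm(self):
        df, grid = self._per_participant(tau=0.0, sigma=0.2, seed=3)
        lmm = emv.fit_factorial_lmm(df, grid,
                                    FactorialModelSpec(response="value"))
        lm = emv.fit_factorial_lm(
            df.groupby("path_id")["value"].mean(), grid,
            FactorialModelSpec(response="value"))
        for name in lm.params.index:
            assert lmm.params[name] == pytest.approx(lm.params[name],
                                                     abs=0.05)

    def test_single_participant_raises(self):
        df, grid = self._per_participant(tau=1.0)
        df = df[df["participant"] == 0]
        with pytest.raises(ValueError):
            emv.fit_factorial_lmm(df, grid,
                                  FactorialModelSpec(response="value"))


class TestMarginalMeans:
    def test_printed_two_factor_cell_means(self):
        """Cells {(a1,b1)=1, (a1,b2)=3, (a2,b1)=5, (a2,b2)=7} give
        EMM(a1)=2, EMM(a2)=6."""
        grid = _grid(a=["1", "2"], b=["1", "2"])
        cells = {("1", "1"): 1.0, ("1", "2"): 3.0,
                 ("2", "1"): 5.0, ("2", "2"): 7.0}
        y = _responses(grid, lambda lv: cells[(lv["a"], lv["b"])])
        m = emv.fit_factorial_lm(y, grid, FactorialModelSpec(response="y"))
        emm = emv.estimated_marginal_means(m, "a")
        by_level = emm.table.set_index("level")["emm"]
        assert by_level["1"] == pytest.approx(2.0)
        assert by_level["2"] == pytest.approx(6.0)

    def test_saturated_model_emms_equal_raw_level_means(self):
        rng = np.random.default_rng(4)
        grid = _grid(a=["0", "1"], b=["x", "y", "z"])
        y = _responses(grid, lambda lv: 0.0) + rng.standard_normal(6)
        m = emv.fit_factorial_lm(y, grid, FactorialModelSpec(response="y"))
        df = paths_to_frame(y.index, grid)
        df["y"] = y.to_numpy()
        for step in ("a", "b"):
            emm = emv.estimated_marginal_means(m, step)
            raw = df.groupby(step, observed=True)["y"].mean()
            for _, row in emm.table.iterrows():
                assert row["emm"] == pytest.approx(raw[row["level"]])

    def test_percent_deviations_sum_to_zero(self):
        rng = np.random.default_rng(5)
        grid = _grid(a=["0", "1"], b=["x", "y", "z"])
        y = _responses(grid, lambda lv: 5.0) + rng.standard_normal(6)
        m = emv.fit_factorial_lm(y, grid, FactorialModelSpec(response="y"))
        for step in ("a", "b"):
            emm = emv.estimated_marginal_means(m, step)
            assert emm.table["pct_deviation"].sum() == pytest.approx(0,
                                                                     abs=1e-8)

    def test_unknown_step_raises(self):
        grid = _grid(a=["0", "1"], b=["x", "y"])
        y = _responses(grid, lambda lv: 1.0 * (lv["a"] == "1"))
        m = emv.fit_factorial_lm(y, grid, FactorialModelSpec(response="y"))
        with pytest.raises(KeyError):
            emv.estimated_marginal_means(m, "nope")


class TestOmnibusAndPairwise:
    def _fit(self, seed=0, effect=0.0, n_rep=10):
        rng = np.random.default_rng(seed)
        grid = _grid(a=["0", "1"], b=["x", "y", "z"])
        reps = []
        for _ in range(n_rep):
            y = _responses(grid, lambda lv: effect * (lv["b"] == "z"))
            reps.append(y + rng.standard_normal(len(y)))
        return emv.fit_factorial_lm(pd.concat(reps), grid,
                                    FactorialModelSpec(response="y",
                                                       interactions=False))

    def test_null_step_type_i_rate_near_alpha(self):
        """Omnibus F on a truly null step rejects at ~ the nominal 5%."""
        rejections = 0
        n_sim = 400
        for seed in range(n_sim):
            m = self._fit(seed=seed, effect=0.0, n_rep=4)
            om, _ = emv.omnibus_and_pairwise(m, "b")
            rejections += om["p"] < 0.05
        rate = rejections / n_sim
        assert abs(rate - 0.05) < 0.035     # ~3 binomial Sds

    def test_real_effect_detected_and_tukey_ordering(self):
        m = self._fit(seed=1, effect=2.0, n_rep=10)
        om, pw = emv.omnibus_and_pairwise(m, "b")
        assert om["p"] < 1e-4
        assert (pw["p_tukey"] >= pw["p_unadjusted"] - 1e-12).all()
        null_pair = pw[(pw.level_a == "x") & (pw.level_b == "y")]
        assert abs(null_pair["estimate"].item()) < 0.5

    def test_single_level_step_raises(self):
        grid = _grid(a=["0", "1"])
        y = _responses(grid, lambda lv: 1.0 * (lv["a"] == "1"))
        m = emv.fit_factorial_lm(y, grid, FactorialModelSpec(response="y"))
        with pytest.raises((KeyError, ValueError)):
            emv.omnibus_and_pairwise(m, "b")


class TestBaselineArtifactLogit:
    def _flags(self, beta, seed=0, grid=None):
        rng = np.random.default_rng(seed)
        grid = grid or {k: list(v) for k, v in emv.DEFAULT_GRID.items()}
        paths = emv.enumerate_paths(grid)
        logit0 = -1.0
        flags = {}
        for p in paths:
            lv = p.as_dict()
            eta = logit0 + beta * (lv.get("detrend") == "linear")
            flags[p.id] = rng.random() < 1 / (1 + np.exp(-eta))
        return pd.Series(flags)

    def test_planted_odds_ratio_detected(self):
        """A step doubling artifact odds: positive coefficient, LRT p < 0.01
        at n_paths = 2592."""
        flags = self._flags(beta=np.log(2.0), seed=6)
        res = emv.baseline_artifact_logit(flags, emv.DEFAULT_GRID)
        assert not res.degenerate and res.converged
        row = res.lrt.set_index("step").loc["detrend"]
        assert row["p"] < 0.01
        coef = [v for k, v in res.params.items() if "detrend" in k]
        assert coef[0] > 0
        # odds ratio near 2
        assert abs(coef[0] - np.log(2.0)) < 0.25

    def test_all_false_flags_degenerate(self):
        grid = {"a": ["0", "1"]}
        flags = pd.Series({p.id: False for p in emv.enumerate_paths(grid)})
        res = emv.baseline_artifact_logit(flags, grid)
        assert res.degenerate
        assert res.lrt is None

    def test_null_type_i_rate(self):
        """LRT on null steps rejects at ~1% with alpha = 0.01."""
        grid = {"a": ["0", "1"], "b": ["x", "y", "z"]}
        big_grid = {k: v * 1 for k, v in grid.items()}
        # replicate the small grid by adding a dummy many-level step
        big_grid["rep"] = [str(i) for i in range(100)]
        rejections, total = 0, 0
        for seed in range(30):
            flags = self._flags(beta=0.0, seed=seed, grid=big_grid)
            res = emv.baseline_artifact_logit(flags, big_grid)
            if res.degenerate:
                continue
            for step in ("a", "b"):
                p = res.lrt.set_index("step").loc[step, "p"]
                rejections += p < 0.01
                total += 1
        assert total >= 40
        assert rejections / total < 0.06
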