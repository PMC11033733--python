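import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from assemblage.markov import (
    MarkovFit,
    assign_states,
    fit_two_state,
    hazard_ratios,
    transition_matrix,
)


def simulate_panel(n_calves, q12, q21, beta_fwd=0.0, beta_bwd=0.0, seed=0,
                   weeks=(1, 2, 3, 6, 8)):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_calves):
        x = float(c % 2)
        state = 1
        prev = None
        for w in weeks:
            if prev is not None:
                p = transition_matrix(
                    q12 * np.exp(beta_fwd * x), q21 * np.exp(beta_bwd * x), w - prev
                )
                state = int(rng.choice([1, 2], p=p[state - 1]))
            rows.append({"calf_id": f"c{c:04d}", "time": w, "state": state, "x": x})
            prev = w
    return pd.DataFrame(rows)


class TestTransitionMatrix:
    def test_t_zero_identity(self):
        np.testing.assert_allclose(transition_matrix(0.3, 0.7, 0.0), np.eye(2))

    def test_zero_rates_identity(self):
        np.testing.assert_allclose(transition_matrix(0.0, 0.0, 5.0), np.eye(2))

    def test_symmetric_closed_form(self):
        q, t = 0.4, 1.7
        p = transition_matrix(q, q, t)
        assert p[0, 0] == pytest.approx((1 + np.exp(-2 * q * t)) / 2)

    def test_matches_matrix_exponential(self):
        q12, q21, t = 0.3, 0.1, 2.0
        gen = np.array([[-q12, q12], [q21, -q21]])
        np.testing.assert_allclose(
            transition_matrix(q12, q21, t), expm(gen * t), atol=1e-10
        )

    def test_rows_sum_to_one(self, rng):
        for _ in range(50):
            q12, q21 = rng.uniform(0, 3, 2)
            t = rng.uniform(0, 10)
            p = transition_matrix(q12, q21, t)
            np.testing.assert_allclose(p.sum(axis=1), [1.0, 1.0], atol=1e-12)

    def test_chapman_kolmogorov(self, rng):
        for _ in range(20):
            q12, q21 = rng.uniform(0.05, 2, 2)
            t1, t2 = rng.uniform(0.1, 4, 2)
            lhs = transition_matrix(q12, q21, t1) @ transition_matrix(q12, q21, t2)
            rhs = transition_matrix(q12, q21, t1 + t2)
            np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_negative_inputs(self):
        with pytest.raises(ValueError):
            transition_matrix(-0.1, 0.2, 1.0)


class TestAssignStates:
    def md(self):
        return pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "calf_id": ["c1", "c1", "c2"],
                "week": [1, 2, 1],
                "treatment": ["CON", "CON", "SCB"],
                "health": ["H", "H", "UH"],
            }
        )

    def test_threshold(self):
        per = pd.Series([0.4, 0.6, 0.5], index=["a", "b", "c"])
        panel = assign_states(per, self.md())
        states = dict(zip(panel["calf_id"].astype(str) + "@" + panel["time"].astype(str), panel["state"]))
        assert states["c1@1.0"] == 2  # 0.4 -> deterministic
        assert states["c1@2.0"] == 1  # 0.6 -> stochastic
        assert states["c2@1.0"] == 1  # tie at 0.5 -> stochastic

    def test_nan_dropped(self):
        per = pd.Series([np.nan, 0.7, 0.2], index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="NaN"):
            panel = assign_states(per, self.md())
        assert len(panel) == 2

    def test_sorted_and_unique(self):
        per = pd.Series([0.7, 0.3, 0.9], index=["b", "a", "c"])
        panel = assign_states(per, self.md())
        for _, sub in panel.groupby("calf_id"):
            assert sub["time"].is_monotonic_increasing
        assert not panel.duplicated(["calf_id", "time"]).any()


class TestFitTwoState:
    def test_recovery_no_covariate_effect(self):
        panel = simulate_panel(600, 0.3, 0.2, seed=1)
        fit = fit_two_state(panel, ["x"])
        assert fit.converged
        assert fit.q12_0 == pytest.approx(0.3, rel=0.3)
        assert fit.q21_0 == pytest.approx(0.2, rel=0.3)
        hr = hazard_ratios(fit)
        fwd = hr[hr.transition == "forward"].iloc[0]
        assert fwd.ci_lo <= 1.0 <= fwd.ci_hi

    def test_recovery_planted_hazard(self):
        beta = float(np.log(1.34))
        hrs = []
        for s in range(5):
            panel = simulate_panel(800, 0.3, 0.2, beta_fwd=beta, seed=10 + s)
            fit = fit_two_state(panel, ["x"])
            hrs.append(np.exp(fit.beta12["x"]))
        assert np.mean(hrs) == pytest.approx(1.34, abs=0.15)

    def test_string_covariate_encoding(self):
        panel = simulate_panel(200, 0.3, 0.2, seed=3)
        panel["health"] = np.where(panel["x"] > 0, "UH", "H")
        fit_num = fit_two_state(panel, ["x"])
        fit_str = fit_two_state(panel, ["health"])
        assert fit_num.beta12["x"] == pytest.approx(fit_str.beta12["health"], abs=1e-4)

    def test_boundary_no_transitions_warns(self):
        rows = []
        for c in range(5):
            for w in (1, 2, 3):
                rows.append({"calf_id": f"c{c}", "time": w, "state": 1, "x": 0.0})
        panel = pd.DataFrame(rows)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_two_state(panel, [])
        assert fit.q12_0 < 0.1

    def test_nonincreasing_times_error(self):
        panel = pd.DataFrame(
            [
                {"calf_id": "c", "time": 2.0, "state": 1},
                {"calf_id": "c", "time": 2.0, "state": 2},
            ]
        )
        with pytest.raises(ValueError, match="strictly increasing"):
            fit_two_state(panel, [])


class TestHazardRatios:
    def fake_fit(self, b12, se12):
        return MarkovFit(
            q12_0=0.3, q21_0=0.2,
            beta12={"health": b12}, beta21={"health": -b12},
            se12={"health": se12}, se21={"health": se12},
            loglik=-10.0, converged=True, vcov=np.eye(4),
            covariates=["health"], n_intervals=100,
        )

    def test_null_effect(self):
        hr = hazard_ratios(self.fake_fit(0.0, 0.1))
        fwd = hr[hr.transition == "forward"].iloc[0]
        assert fwd.hr == pytest.approx(1.0)
        assert fwd.ci_lo < 1.0 < fwd.ci_hi

    def test_wald_arithmetic(self):
        hr = hazard_ratios(self.fake_fit(np.log(2), 0.1))
        fwd = hr[hr.transition == "forward"].iloc[0]
        assert fwd.hr == pytest.approx(2.0)
        assert fwd.ci_lo == pytest.approx(np.exp(np.log(2) - 1.959963984540054 * 0.1))
        assert fwd.ci_hi == pytest.approx(np.exp(np.log(2) + 1.959963984540054 * 0.1))

    def test_direction_labels(self):
        hr = hazard_ratios(self.fake_fit(0.5, 0.1))
        assert list(hr.transition) == ["forward", "backward"]
        assert hr.iloc[0].hr > 1 > hr.iloc[1].hr
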