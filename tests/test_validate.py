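"""Tests of recovery, z-scores, ANOVA precision and Monte Carlo uncertainty."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spq
from spq.validate import (
    ReplicateDesign,
    UncertaintyBudget,
    UncertaintyComponent,
    anova_precision,
    mc_uncertainty,
    recovery,
    z_score,
)


class TestRecovery:
    def test_full_recovery(self):
        assert recovery(34.4, 34.4) == 100.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            recovery(1.0, 0.0)

    @given(
        st.floats(min_value=0.1, max_value=1e6),
        st.floats(min_value=0.1, max_value=1e6),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, measured, reference, scale):
        assert recovery(scale * measured, scale * reference) == pytest.approx(
            recovery(measured, reference), rel=1e-9
        )


class TestZScore:
    def test_zero_at_assigned_value(self):
        assert z_score(100.0, 100.0, 40.0) == 0.0

    def test_formula(self):
        assert z_score(112.0, 100.0, 40.0) == pytest.approx(0.3)

    def test_sign_flips_below_assigned(self):
        assert z_score(88.0, 100.0, 40.0) == -z_score(112.0, 100.0, 40.0)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            z_score(1.0, 1.0, 0.0)


def _oracle_anova(values, labels):
    """From-scratch sums-of-squares decomposition, written independently of
    the implementation (explicit loops, textbook formulas)."""
    days = sorted(set(labels))
    groups = {d: [v for v, l in zip(values, labels) if l == d] for d in days}
    N = len(values)
    p = len(days)
    grand = sum(values) / N
    ss_w = sum((v - sum(g) / len(g)) ** 2 for d, g in groups.items() for v in g)
    ss_b = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups.values())
    ms_w = ss_w / (N - p)
    ms_b = ss_b / (p - 1)
    n0 = (N - sum(len(g) ** 2 for g in groups.values()) / N) / (p - 1)
    s_r2 = ms_w
    s_b2 = max(0.0, (ms_b - ms_w) / n0)
    return {
        "rsd_r": 100 * np.sqrt(s_r2) / abs(grand),
        "rsd_ip": 100 * np.sqrt(s_r2 + s_b2) / abs(grand),
        "clamped": ms_b < ms_w,
    }


class TestAnovaPrecision:
    def test_identical_values_have_zero_rsd(self):
        design = ReplicateDesign(np.full(15, 50.0), np.repeat(np.arange(5), 3))
        res = anova_precision(design)
        assert res.rsd_repeatability == 0.0
        assert res.rsd_intermediate == 0.0

    def test_matches_sums_of_squares_oracle(self):
        """Random small designs (<=5 days x <=5 reps, balanced and unbalanced)
        agree with the from-scratch oracle to 1e-10."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            p = rng.integers(2, 6)
            labels, values = [], []
            for d in range(p):
                n_d = rng.integers(2, 6)
                labels += [d] * n_d
                values += list(rng.normal(50, 3, n_d))
            res = anova_precision(ReplicateDesign(np.array(values), np.array(labels)))
            oracle = _oracle_anova(values, labels)
            assert res.rsd_repeatability == pytest.approx(oracle["rsd_r"], abs=1e-10)
            assert res.rsd_intermediate == pytest.approx(oracle["rsd_ip"], abs=1e-10)
            assert res.clamped == oracle["clamped"]

    def test_matches_statsmodels_mean_squares(self):
        """Balanced design cross-checked against statsmodels one-way ANOVA."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "value": rng.normal(50, 2, 15) + np.repeat(rng.normal(0, 1, 5), 3),
                "day": np.repeat([f"d{i}" for i in range(5)], 3),
            }
        )
        table = sm.stats.anova_lm(ols("value ~ C(day)", data=df).fit())
        ms_within = table.loc["Residual", "mean_sq"]
        res = anova_precision(ReplicateDesign(df["value"].to_numpy(), df["day"].to_numpy()))
        assert res.within_day_variance == pytest.approx(ms_within, rel=1e-10)

    def test_recovers_known_variance_components(self):
        """5 days x 3 reps with sigma_w=2, sigma_b=1 about mean 50: mean
        recovered RSDs across 500 seeds within 10% relative of truth."""
        sigma_w, sigma_b, mu, n_rep = 2.0, 1.0, 50.0, 3
        rsd_r_true = 100 * sigma_w / mu
        rsd_ip_true = 100 * np.sqrt(sigma_w**2 + sigma_b**2) / mu
        rng = np.random.default_rng(99)
        rs, ips = [], []
        for _ in range(500):
            day_effects = rng.normal(0, sigma_b, 5)
            values = (
                mu
                + np.repeat(day_effects, n_rep)
                + rng.normal(0, sigma_w, 5 * n_rep)
            )
            res = anova_precision(ReplicateDesign(values, np.repeat(np.arange(5), n_rep)))
            rs.append(res.rsd_repeatability)
            ips.append(res.rsd_intermediate)
        assert np.mean(rs) == pytest.approx(rsd_r_true, rel=0.10)
        assert np.mean(ips) == pytest.approx(rsd_ip_true, rel=0.10)

    def test_clamping_when_between_day_variance_absent(self):
        """With sigma_b = 0 the between-day mean square falls below the
        within-day mean square in roughly half the seeds; the clamp flag is
        set and the total RSD is available as the fallback."""
        rng = np.random.default_rng(31)
        clamped = 0
        n_rep = 200
        for _ in range(n_rep):
            values = rng.normal(50, 2, 15)
            res = anova_precision(ReplicateDesign(values, np.repeat(np.arange(5), 3)))
            clamped += res.clamped
            if res.clamped:
                assert res.rsd_intermediate == res.rsd_repeatability
                assert res.total_rsd > 0
        assert 0.3 < clamped / n_rep < 0.8

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            anova_precision(ReplicateDesign(np.arange(5.0), np.zeros(5)))


class TestMcUncertainty:
    def test_single_normal_identity_measurand(self):
        """One 5%-relative normal input through the identity: U = k*5% = 10%."""
        budget = UncertaintyBudget(
            components=[UncertaintyComponent("x", "normal", (100.0, 5.0))],
            measurand=lambda d: d["x"],
            n_draws=200_000,
            seed=1,
        )
        res = mc_uncertainty(budget)
        assert res.expanded_uncertainty_pct == pytest.approx(10.0, abs=0.2)
        assert res.coverage_factor == 2.0

    def test_multiplicative_inputs_match_quadrature(self):
        """3% and 4% relative inputs entering multiplicatively: U ~ 2*5%."""
        budget = UncertaintyBudget(
            components=[
                UncertaintyComponent("a", "normal", (1.0, 0.03)),
                UncertaintyComponent("b", "normal", (50.0, 2.0)),
            ],
            measurand=lambda d: d["a"] * d["b"],
            n_draws=200_000,
            seed=2,
        )
        res = mc_uncertainty(budget)
        assert res.expanded_uncertainty_pct == pytest.approx(10.0, abs=0.2)
        # shares split 9:16 between the two components
        assert res.component_shares["a"] == pytest.approx(0.36, abs=0.02)
        assert res.component_shares["b"] == pytest.approx(0.64, abs=0.02)

    def test_poisson_counting_component(self):
        """N=1000 measured particles contribute ~1/sqrt(1000) = 3.2% relative."""
        budget = UncertaintyBudget(
            components=[UncertaintyComponent("n", "poisson", (1000.0,))],
            measurand=lambda d: d["n"],
            n_draws=200_000,
            seed=3,
        )
        res = mc_uncertainty(budget)
        assert res.rel_standard_uncertainty_pct == pytest.approx(3.162, abs=0.1)

    def test_convergence_with_draw_count(self):
        """Doubling n_draws moves U by less than 3 combined MC standard errors."""
        def make(n, seed):
            return UncertaintyBudget(
                components=[UncertaintyComponent("x", "normal", (100.0, 5.0))],
                measurand=lambda d: d["x"],
                n_draws=n,
                seed=seed,
            )

        u1 = mc_uncertainty(make(50_000, 11)).expanded_uncertainty_pct
        u2 = mc_uncertainty(make(100_000, 12)).expanded_uncertainty_pct
        se = 10.0 / np.sqrt(2 * 50_000)
        assert abs(u1 - u2) < 3 * np.sqrt(2) * se

    def test_budget_validation(self):
        comp = UncertaintyComponent("x", "normal", (1.0, 0.1))
        with pytest.raises(ValueError):
            UncertaintyBudget([comp], lambda d: d["x"], n_draws=100)
        with pytest.raises(ValueError):
            UncertaintyBudget([comp, comp], lambda d: d["x"])
        with pytest.raises(ValueError):
            mc_uncertainty(
                UncertaintyBudget(
                    [UncertaintyComponent("x", "cauchy", (0.0, 1.0))],
                    lambda d: d["x"],
                )
            )

    def test_triangular_and_uniform_components(self):
        budget = UncertaintyBudget(
            components=[
                UncertaintyComponent("u", "uniform", (0.9, 1.1)),
                UncertaintyComponent("t", "triangular", (0.9, 1.0, 1.1)),
            ],
            measurand=lambda d: d["u"] * d["t"],
            n_draws=100_000,
            seed=5,
        )
        res = mc_uncertainty(budget)
        # quadrature of 0.1/sqrt(3) and 0.1/sqrt(6) relative SDs, times k=2
        expected = 2 * 100 * np.sqrt(0.1**2 / 3 + 0.1**2 / 6)
        assert res.expanded_uncertainty_pct == pytest.approx(expected, abs=0.2)
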