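"""Estimation chain: smoothing, closed-form estimators, fit, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from schwannoma.inference import (
    VariantCountData,
    VestibularSchwannomaModel,
    bootstrap_parameters,
    estimate_n_gfx,
    estimate_r_loh,
    fit_cubic,
    histogram_mode,
    mortality_correct,
    smooth_frequency,
    solve_u_from_A,
)


class TestSmoothing:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(17, 23, 17.5 / 24), (0, 32, 0.5 / 33), (5, 5, 5.5 / 6)],
    )
    def test_known_values(self, k, n, expected):
        assert smooth_frequency(k, n) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(min_value=1, max_value=500), st.data())
    def test_never_saturates(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        f = smooth_frequency(k, n)
        assert 0.0 < f < 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            smooth_frequency(5, 4)
        with pytest.raises(ValueError):
            smooth_frequency(0, 0)


class TestClosedFormEstimators:
    def test_n_gfx_from_study_counts(self):
        n_gfx = estimate_n_gfx(17.5 / 24, 0.5 / 33, 85.0)
        assert n_gfx == pytest.approx(2002.0, rel=5e-4)

    def test_equal_frequencies_give_zero(self):
        assert estimate_n_gfx(0.3, 0.3, 85.0) == 0.0
        assert estimate_r_loh(0.3, 0.3) == 0.0

    def test_zero_f_smarcb1_diverges_with_helpful_error(self):
        with pytest.raises(ZeroDivisionError, match="smoothing"):
            estimate_n_gfx(0.7, 0.0, 85.0)

    def test_inconsistent_ordering_rejected(self):
        with pytest.raises(ValueError):
            estimate_n_gfx(0.1, 0.2, 85.0)

    @given(
        st.floats(min_value=0.01, max_value=0.9),
        st.floats(min_value=1e-4, max_value=1.0),
        st.floats(min_value=1.0, max_value=500.0),
    )
    def test_n_gfx_matches_direct_formula(self, f_loh, ratio, n_s):
        f_s = f_loh * ratio
        assert estimate_n_gfx(f_loh, f_s, n_s) == pytest.approx(
            0.5 * n_s * (f_loh - f_s) / f_s
        )

    def test_r_loh_multiplier_magnitude(self):
        # with the study frequencies the u-multiplier is ~4.5e3 per year
        r = estimate_r_loh(17.5 / 24, 0.5 / 33, u=1.0)
        assert r == pytest.approx(4.5e3, rel=0.01)

    def test_r_loh_linear_in_u(self):
        r1 = estimate_r_loh(17.5 / 24, 0.5 / 33, u=4.48e-10)
        r2 = estimate_r_loh(17.5 / 24, 0.5 / 33, u=2 * 4.48e-10)
        assert r2 == pytest.approx(2 * r1)
        assert r1 == pytest.approx(2.03e-6, rel=0.01)

    def test_saturated_f_loh_rejected(self):
        with pytest.raises(ValueError):
            estimate_r_loh(1.0, 0.01)


class TestMortalityCorrection:
    def test_immortal_population_only_rescales(self):
        inc = pd.DataFrame({"age": [20.0, 50.0, 90.0], "cum_incidence": [1e-6, 5e-6, 2e-5]})
        lt = pd.DataFrame({"age": [0.0, 100.0], "survivorship": [1.0, 1.0]})
        out = mortality_correct(inc, lt)
        assert out["age"].max() <= 80.0
        np.testing.assert_allclose(
            out["cum_incidence"], [0.85e-6, 0.85 * 5e-6], rtol=1e-12
        )

    def test_missing_life_table_ages_rejected(self):
        inc = pd.DataFrame({"age": [90.0], "cum_incidence": [1e-5]})
        lt = pd.DataFrame({"age": [0.0, 60.0], "survivorship": [1.0, 0.9]})
        with pytest.raises(ValueError):
            mortality_correct(inc, lt)

    def test_recovers_cubic_from_mortality_thinned_curve(self):
        # analytic thinned curve: dI = S(t) 3A t^2 dt on a fine grid
        A = 2.26e-11 / 0.85
        ages = np.linspace(0.5, 100.0, 200)
        lam = 0.01
        surv = np.exp(-lam * ages)
        mids = np.concatenate([[ages[0] / 2], (ages[1:] + ages[:-1]) / 2])
        incr = np.exp(-lam * mids) * 3 * A * mids ** 2 * np.diff(ages, prepend=0.0)
        inc = pd.DataFrame({"age": ages, "cum_incidence": np.cumsum(incr)})
        lt = pd.DataFrame({"age": np.arange(101.0), "survivorship": np.exp(-lam * np.arange(101.0))})
        out = mortality_correct(inc, lt)
        fit = fit_cubic(out)
        assert fit.A == pytest.approx(2.26e-11, rel=5e-3)


class TestCubicFit:
    def test_exact_recovery_on_noise_free_curve(self):
        t = np.arange(1.0, 81.0)
        df = pd.DataFrame({"age": t, "cum_incidence": 2.26e-11 * t ** 3})
        fit = fit_cubic(df)
        assert fit.A == pytest.approx(2.26e-11, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_scale_equivariance(self):
        t = np.arange(1.0, 41.0)
        rng = np.random.default_rng(3)
        y = 1e-11 * t ** 3 * (1 + 0.05 * rng.standard_normal(len(t)))
        a1 = fit_cubic(pd.DataFrame({"age": t, "cum_incidence": y})).A
        a2 = fit_cubic(pd.DataFrame({"age": t, "cum_incidence": 7.0 * y})).A
        assert a2 == pytest.approx(7.0 * a1, rel=1e-9)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            fit_cubic(pd.DataFrame({"age": [0.0, 0.0, 0.0], "cum_incidence": [0, 0, 0]}))


class TestUInversion:
    def test_paper_scale_inversion(self):
        u = solve_u_from_A(2.26e-11)
        assert u == pytest.approx(4.48e-10, rel=0.01)

    def test_forward_inverse_round_trip(self):
        from schwannoma.incidence import IncidenceModelParams
        from schwannoma.inference import estimate_n_gfx, estimate_r_loh

        fL, fS = 17.5 / 24, 0.5 / 33
        u_star = 3.3e-10
        p = IncidenceModelParams(
            u=u_star,
            n_gfx=estimate_n_gfx(fL, fS, 85.0),
            r_loh=estimate_r_loh(fL, fS, u=u_star),
        )
        assert solve_u_from_A(p.A, f_loh=fL, f_smarcb1=fS) == pytest.approx(
            u_star, rel=1e-12
        )

    def test_cube_root_scaling(self):
        assert solve_u_from_A(8 * 2.26e-11) == pytest.approx(
            2 * solve_u_from_A(2.26e-11), rel=1e-12
        )

    def test_nonpositive_A_rejected(self):
        with pytest.raises(ValueError):
            solve_u_from_A(0.0)


class TestBootstrap:
    LOH = VariantCountData("LOH-22q", 17, 23)
    SM = VariantCountData("SMARCB1", 0, 32)

    def test_reproducible_under_seed(self):
        a = bootstrap_parameters(self.LOH, self.SM, n_reps=500, seed=11)
        b = bootstrap_parameters(self.LOH, self.SM, n_reps=500, seed=11)
        np.testing.assert_array_equal(a["u"].values, b["u"].values)

    def test_intervals_tighten_with_tenfold_samples(self):
        small = bootstrap_parameters(self.LOH, self.SM, n_reps=4000, seed=5)
        big = bootstrap_parameters(
            VariantCountData("LOH-22q", 170, 230),
            VariantCountData("SMARCB1", 0, 320),
            n_reps=4000,
            seed=5,
        )
        for name in ("n_gfx", "u", "r_loh"):
            # scale-free comparison: the estimand's scale changes with the
            # pseudocount fraction, so compare widths relative to the point
            w_small = (small[name].ci_high - small[name].ci_low) / small[name].point
            w_big = (big[name].ci_high - big[name].ci_low) / big[name].point
            assert w_big < w_small

    def test_pseudocount_scheme_reports_exclusions(self):
        bs = bootstrap_parameters(self.LOH, self.SM, n_reps=2000, seed=2, scheme="pseudocount")
        # with 0/32 positives the pseudo-observation is missed in ~(32/33)^33
        # of draws, giving f* = 0 replicates that must be excluded
        assert 0.2 < bs["u"].excluded_fraction < 0.5

    def test_indicator_scheme_excludes_nothing(self):
        bs = bootstrap_parameters(self.LOH, self.SM, n_reps=2000, seed=2)
        assert bs["u"].excluded_fraction == 0.0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_parameters(self.LOH, self.SM, n_reps=10, seed=1, scheme="jackknife")

    def test_histogram_mode_finds_bulk(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.1, 5000), rng.normal(5, 1.0, 500)])
        assert abs(histogram_mode(x)) < 0.5


class TestModelResults:
    def test_fixed_A_chain(self):
        res = VestibularSchwannomaModel.from_counts().fit()
        assert res.n_gfx == pytest.approx(2002.8, rel=1e-3)
        assert res.u == pytest.approx(4.46e-10, rel=1e-2)
        assert res.p_loh == pytest.approx(res.r_loh / 25.5, rel=1e-12)

    def test_summary_contains_estimates(self):
        res = VestibularSchwannomaModel.from_counts().fit(n_boot=500, seed=3)
        text = res.summary()
        assert "n_GFX" in text and "r_LOH" in text and "95% CI" in text
        ci = res.conf_int()
        assert set(ci.index) == {"n_gfx", "u", "r_loh", "n_tsx"}
        assert (ci["ci_low"] < ci["ci_high"]).all()

    def test_incidence_params_round_trip(self):
        from schwannoma.incidence import predicted_variant_frequencies

        res = VestibularSchwannomaModel.from_counts().fit()
        f = predicted_variant_frequencies(res.incidence_params())
        assert f["f_LOH"] == pytest.approx(res.f_loh, rel=1e-9)

    def test_requires_data_or_A(self):
        with pytest.raises(ValueError):
            VestibularSchwannomaModel(
                loh=VariantCountData("L", 17, 23),
                smarcb1=VariantCountData("S", 0, 32),
            )
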