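"""Two-stage genetic-gain estimation: stage-1 BLUEs and stage-2 regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stressgain.simulate import (
    CONDITIONS,
    ProgramConfig,
    TruthRecord,
    build_program,
)
from stressgain.trend import (
    DegenerateDesignError,
    percent_gain,
    stage1_means,
    stage2_trend,
)

from _oracles import gls_estimates, marginal_covariance, sum_to_zero_design, wls_fit


def _means_table(years, estimates, ses, cls="DTSTR"):
    n = len(years)
    return pd.DataFrame(
        {
            "hybrid": [f"H{i:03d}" for i in range(n)],
            "hybrid_class": cls,
            "condition": "MDS",
            "estimate": np.asarray(estimates, float),
            "se": np.asarray(ses, float),
            "weight": 1.0 / np.asarray(ses, float) ** 2,
            "first_year": list(years),
            "years_tested": 1,
            "n_plots": 3,
        }
    )


class TestStage2:
    def test_collinear_points_exact_slope(self):
        m = _means_table([2012, 2013, 2014], [4000, 4050, 4100], [10, 10, 10])
        g = stage2_trend(m)
        assert g.slope == pytest.approx(50.0, abs=1e-9)
        assert g.first_year_baseline == pytest.approx(4000.0, abs=1e-6)
        assert g.percent_gain == pytest.approx(100 * 50 / 4000, abs=1e-6)

    def test_equal_weights_reduce_to_ols(self):
        rng = np.random.default_rng(0)
        yrs = rng.integers(2012, 2020, 12)
        est = 3500 + 40 * (yrs - 2012) + rng.normal(0, 150, 12)
        m = _means_table(yrs, est, np.full(12, 25.0))
        g = stage2_trend(m)
        b = np.polyfit(yrs.astype(float), est, 1)
        assert g.slope == pytest.approx(b[0], rel=1e-9)

    def test_heteroscedastic_matches_weighted_normal_equations(self):
        yrs = np.array([2012, 2013, 2014, 2015, 2016, 2017])
        est = np.array([3000.0, 3120, 3075, 3260, 3350, 3390])
        ses = np.array([20.0, 55, 30, 80, 15, 60])
        m = _means_table(yrs, est, ses)
        g = stage2_trend(m)
        icpt, slope, se = wls_fit(est, yrs.astype(float), 1 / ses**2)
        assert g.slope == pytest.approx(slope, abs=1e-10 * abs(slope))
        assert g.intercept == pytest.approx(icpt, rel=1e-9)
        assert g.slope_se == pytest.approx(se, rel=1e-9)
        assert 0 < g.p <= 1

    def test_check_classes_excluded_by_default(self):
        m = pd.concat(
            [
                _means_table([2012, 2014, 2016, 2018],
                             [3000, 3100, 3200, 3300], [10] * 4),
                _means_table([2012], [9000], [1], cls="LOCAL").assign(
                    hybrid="CHK"
                ),
            ],
            ignore_index=True,
        )
        g = stage2_trend(m)
        assert g.n_hybrids == 4
        assert g.slope == pytest.approx(50.0, abs=1e-8)
        pooled = stage2_trend(m, include_classes=None)
        assert pooled.n_hybrids == 5
        assert pooled.slope != pytest.approx(50.0, abs=1.0)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DegenerateDesignError):
            stage2_trend(_means_table([2012, 2012, 2012],
                                      [1, 2, 3], [1, 1, 1]))
        with pytest.raises(DegenerateDesignError):
            stage2_trend(_means_table([2012, 2013], [1, 2], [1, 1]))

    @given(shift=st.integers(-50, 50))
    def test_shift_of_first_years_leaves_gain_invariant(self, shift):
        yrs = np.array([2012, 2013, 2014, 2015, 2016, 2017])
        est = np.array([3000.0, 3120, 3075, 3260, 3350, 3390])
        ses = np.array([20.0, 55, 30, 80, 15, 60])
        g0 = stage2_trend(_means_table(yrs, est, ses))
        g1 = stage2_trend(_means_table(yrs + shift, est, ses))
        assert g1.slope == pytest.approx(g0.slope, rel=1e-9)
        assert g1.first_year_baseline == pytest.approx(
            g0.first_year_baseline, rel=1e-9
        )
        assert g1.percent_gain == pytest.approx(g0.percent_gain, rel=1e-9)


class TestPercentGain:
    def test_zero_slope(self):
        assert percent_gain(0.0, 4000.0, 2012) == 0.0

    def test_printed_example(self):
        assert percent_gain(50.0, -96550.0, 2012) == pytest.approx(
            1.2346, abs=5e-5
        )

    def test_unit_case(self):
        assert percent_gain(10.0, 1000.0, 0) == pytest.approx(1.0)

    def test_nonpositive_baseline_undefined(self):
        assert np.isnan(percent_gain(50.0, -200_000.0, 2012))


def _noise_free_program(trend=60.0):
    zero = {c: 0.0 for c in CONDITIONS}
    truth = TruthRecord(
        sigma2_G=0, sigma2_GY=0, sigma2_S=0, sigma2_Y=0, sigma2_R=0,
        sigma2_B=0,
        residual_variance_per_condition=dict(zero),
        residual_lognorm_sd=0.0, low_h2_fraction={},
        trend_per_condition={"MDS": trend},
    )
    cfg = ProgramConfig(
        conditions=("MDS",),
        tenure_distribution={"DTSTR": {1: 4, 2: 3, 8: 2}, "LOCAL": {8: 1}},
        truth=truth,
    )
    return build_program(cfg, seed=1)


class TestStage1:
    def test_noise_free_recovery_is_exact(self):
        plots, truth = _noise_free_program()
        m = stage1_means(plots, "MDS")
        tv = truth.genetic_value("MDS") + truth.truth.condition_mean["MDS"]
        merged = m.set_index("hybrid").join(tv.rename("truth"))
        assert np.allclose(merged.estimate, merged.truth, atol=1e-6)
        g = stage2_trend(m)
        assert g.slope == pytest.approx(60.0, abs=1e-6)

    def test_invariant_to_year_relabeling(self, small_program):
        plots, _ = small_program
        m1 = stage1_means(plots, "MDS")
        relabeled = plots.copy()
        relabeled["year"] = relabeled["year"].map(
            lambda y: {2012: 2019, 2019: 2012}.get(y, y)
        )
        m2 = stage1_means(relabeled, "MDS")
        a = m1.set_index("hybrid").estimate
        b = m2.set_index("hybrid").estimate
        assert np.allclose(a, b.loc[a.index], atol=1e-4)

    def test_unbalanced_means_match_dense_gls(self):
        """Small unbalanced single-location layout: stage-1 BLUEs equal an
        explicit GLS at the fitted covariance."""
        rng = np.random.default_rng(12)
        rows = []
        for hyb, (fy, tenure) in {
            "H1": (2012, 3), "H2": (2012, 1), "H3": (2013, 2),
            "H4": (2013, 1), "H5": (2014, 1), "H6": (2012, 3),
        }.items():
            for yr in range(fy, fy + tenure):
                for rep in (1, 2):
                    rows.append(
                        dict(condition="MDS", year=yr, location="IK",
                             replicate=rep, block=1, hybrid=hyb,
                             hybrid_class="DTSTR")
                    )
        plots = pd.DataFrame(rows)
        gv = dict(H1=0, H2=150, H3=60, H4=-80, H5=220, H6=40)
        ye = {2012: 0.0, 2013: 250.0, 2014: -120.0}
        plots["grain_yield"] = (
            3000.0
            + plots.hybrid.map(gv)
            + plots.year.map(ye)
            + rng.normal(0, 80, len(plots))
        )
        m = stage1_means(plots, "MDS")
        fit = m.attrs["fit"]
        resid = plots["year"].map(fit.residual_varcomp).to_numpy(float)
        V = marginal_covariance(
            plots,
            [("year", "replicate"), ("hybrid", "year")],
            [fit.varcomp["year:location:replicate"],
             fit.varcomp["hybrid:year"]],
            resid,
        )
        X = sum_to_zero_design(plots, ["hybrid", "year"])
        beta, cov = gls_estimates(plots.grain_yield.to_numpy(), X, V)
        hybs = sorted(plots.hybrid.unique())
        for _, row in m.iterrows():
            j = hybs.index(row.hybrid)
            c = np.zeros(X.shape[1])
            c[0] = 1.0
            if j < len(hybs) - 1:
                c[1 + j] = 1.0
            else:
                c[1:len(hybs)] = -1.0
            assert row.estimate == pytest.approx(float(c @ beta), rel=1e-5)
            assert row.se == pytest.approx(
                float(np.sqrt(c @ cov @ c)), rel=1e-3
            )

    def test_single_seed_recovery_within_sampling_error(self, small_program):
        plots, truth = small_program
        m = stage1_means(plots, "MDS")
        g = stage2_trend(m)
        true_slope = truth.truth.trend_per_condition["MDS"]
        assert abs(g.slope - true_slope) < 4 * g.slope_se
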