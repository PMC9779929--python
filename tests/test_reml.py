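"""REML core: component estimation, BLUEs/BLUPs, and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from stressgain.reml import ModelSpec, adjusted_means, blup_pev, fit_lmm

from _oracles import (
    anova_oneway_components,
    dense_reml_criterion,
    gls_estimates,
    marginal_covariance,
    sum_to_zero_design,
)


def test_balanced_oneway_matches_anova_closed_form(toy_oneway):
    fit = fit_lmm(toy_oneway, ModelSpec(response="y", random_terms=("geno",)))
    assert fit.converged
    assert fit.varcomp["geno"] == pytest.approx(15.0, abs=1e-4)
    assert fit.residual_varcomp["all"] == pytest.approx(2.0, abs=1e-4)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_balanced_oneway_reproduces_moment_estimators(seed):
    """REML equals ANOVA method-of-moments on balanced one-way layouts
    with interior solutions (to 1e-6 relative)."""
    rng = np.random.default_rng(seed)
    k, n = 12, 6
    g = rng.normal(0, 3.0, k)
    data = pd.DataFrame(
        {
            "geno": np.repeat([f"g{i}" for i in range(k)], n),
            "y": np.repeat(g, n) + rng.normal(0, 1.0, k * n),
        }
    )
    sg2, se2 = anova_oneway_components(
        [data.loc[data.geno == f"g{i}", "y"] for i in range(k)]
    )
    assume_interior = sg2 > 0.05
    fit = fit_lmm(data, ModelSpec(response="y", random_terms=("geno",)))
    if assume_interior:
        assert fit.varcomp["geno"] == pytest.approx(sg2, rel=1e-5)
        assert fit.residual_varcomp["all"] == pytest.approx(se2, rel=1e-5)


def test_constant_response_all_components_zero(toy_oneway):
    data = toy_oneway.assign(y=7.5)
    fit = fit_lmm(data, ModelSpec(response="y", random_terms=("geno",)))
    assert fit.varcomp["geno"] == 0.0
    assert fit.beta[0] == pytest.approx(7.5)
    assert "geno" in fit.boundary


def test_reml_criterion_matches_dense_marginal_formula():
    """MME-based criterion equals the dense covariance-matrix REML
    criterion, and the optimizer's solution is not beaten on a grid."""
    rng = np.random.default_rng(42)
    n = 24
    data = pd.DataFrame(
        {
            "geno": rng.choice([f"g{i}" for i in range(6)], n),
            "env": np.repeat(["e1", "e2"], n // 2),
        }
    )
    gv = {f"g{i}": rng.normal(0, 1.5) for i in range(6)}
    noise = np.where(data.env == "e1", rng.normal(0, 0.8, n),
                     rng.normal(0, 2.0, n))
    data["y"] = data.geno.map(gv) + noise
    spec = ModelSpec(response="y", random_terms=("geno",),
                     residual_groups="env", pool_small_groups=0)
    fit = fit_lmm(data, spec)
    y = data["y"].to_numpy()
    X = np.ones((n, 1))

    def oracle(theta):
        sg2, s_e1, s_e2 = theta
        resid = np.where(data.env == "e1", s_e1, s_e2)
        V = marginal_covariance(data, ["geno"], [sg2], resid)
        return dense_reml_criterion(y, X, V)

    theta_hat = np.array(
        [fit.varcomp["geno"], fit.residual_varcomp["e1"],
         fit.residual_varcomp["e2"]]
    )
    # route equivalence at several points
    for mult in ([1, 1, 1], [1.5, 0.7, 1.2], [0.5, 2.0, 0.9]):
        th = theta_hat * np.asarray(mult)
        assert fit.objective(th) == pytest.approx(oracle(th), rel=1e-9)
    # optimality: no grid point beats the returned optimum
    f_hat = fit.objective(theta_hat)
    for da in (0.8, 0.9, 1.0, 1.1, 1.25):
        for db in (0.8, 1.0, 1.2):
            for dc in (0.8, 1.0, 1.2):
                th = theta_hat * np.array([da, db, dc])
                assert oracle(th) >= f_hat - 1e-6


def test_heterogeneous_machinery_reduces_to_homogeneous(toy_oneway):
    data = toy_oneway.assign(grp="only")
    hom = fit_lmm(data, ModelSpec(response="y", random_terms=("geno",)))
    het = fit_lmm(
        data,
        ModelSpec(response="y", random_terms=("geno",),
                  residual_groups="grp", pool_small_groups=0),
    )
    assert het.varcomp["geno"] == pytest.approx(hom.varcomp["geno"], rel=1e-6)
    assert het.residual_varcomp["only"] == pytest.approx(
        hom.residual_varcomp["all"], rel=1e-6
    )
    assert het.reml_loglik == pytest.approx(hom.reml_loglik, abs=1e-6)


def test_loglik_invariant_to_factor_level_relabeling():
    """Relabeling fixed-factor levels permutes the contrast basis but must
    not change the restricted likelihood or the variance components."""
    rng = np.random.default_rng(5)
    n = 40
    data = pd.DataFrame(
        {
            "hyb": rng.choice(list("abcd"), n),
            "yr": rng.choice(["y1", "y2"], n),
        }
    )
    data["y"] = (
        data.hyb.map({"a": 0, "b": 1, "c": 2, "d": 3.0})
        + data.yr.map({"y1": 0, "y2": 0.5})
        + rng.normal(0, 1, n)
    )
    spec = ModelSpec(response="y", fixed_terms=("hyb", "yr"),
                     random_terms=("hyb:yr",))
    f1 = fit_lmm(data, spec)
    relabel = {"a": "z_last", "b": "m", "c": "a0", "d": "q"}
    data2 = data.assign(hyb=data.hyb.map(relabel))
    f2 = fit_lmm(data2, spec)
    assert f2.reml_loglik == pytest.approx(f1.reml_loglik, abs=1e-6)
    assert f2.varcomp["hyb:yr"] == pytest.approx(
        f1.varcomp["hyb:yr"], rel=1e-5, abs=1e-8
    )


class TestAdjustedMeans:
    def test_oneway_fixed_balanced_equals_group_means(self, toy_oneway):
        fit = fit_lmm(toy_oneway, ModelSpec(response="y",
                                            fixed_terms=("geno",)))
        means = {m.level: m.estimate for m in adjusted_means(fit, "geno")}
        assert means == pytest.approx({"A": 11.0, "B": 15.0, "C": 19.0})

    def test_two_crossed_factors_balanced(self):
        """2x2 balanced layout: adjusted means equal per-level averages."""
        data = pd.DataFrame(
            {
                "f1": ["a", "a", "b", "b"] * 2,
                "f2": ["u", "v", "u", "v"] * 2,
                "y": [1.0, 3, 5, 7, 2, 4, 6, 8],
            }
        )
        fit = fit_lmm(data, ModelSpec(response="y", fixed_terms=("f1", "f2")))
        m1 = {m.level: m.estimate for m in adjusted_means(fit, "f1")}
        assert m1["a"] == pytest.approx(data.loc[data.f1 == "a", "y"].mean())
        assert m1["b"] == pytest.approx(data.loc[data.f1 == "b", "y"].mean())

    def test_unbalanced_matches_explicit_gls(self):
        """Hybrid missing from one year: BLUEs and SEs must equal a dense
        GLS computed from the fitted covariance."""
        rng = np.random.default_rng(7)
        rows = []
        for hyb in ["h1", "h2", "h3", "h4"]:
            for yr in ["y1", "y2", "y3"]:
                if hyb == "h1" and yr != "y2":
                    continue  # h1 observed in a single year
                for rep in range(3):
                    rows.append((hyb, yr, rep))
        data = pd.DataFrame(rows, columns=["hyb", "yr", "rep"])
        data["y"] = (
            data.hyb.map({"h1": 10.0, "h2": 11, "h3": 12, "h4": 14})
            + data.yr.map({"y1": -1.0, "y2": 0, "y3": 1.5})
            + rng.normal(0, 0.7, len(data))
        )
        spec = ModelSpec(response="y", fixed_terms=("hyb", "yr"),
                         random_terms=("hyb:yr",))
        fit = fit_lmm(data, spec)
        V = marginal_covariance(
            data, [("hyb", "yr")], [fit.varcomp["hyb:yr"]],
            np.full(len(data), fit.residual_varcomp["all"]),
        )
        X = sum_to_zero_design(data, ["hyb", "yr"])
        beta, cov = gls_estimates(data["y"].to_numpy(), X, V)
        means = adjusted_means(fit, "hyb")
        levels = sorted(data.hyb.unique())
        for m in means:
            j = levels.index(m.level)
            c = np.zeros(X.shape[1])
            c[0] = 1.0
            if j < len(levels) - 1:
                c[1 + j] = 1.0
            else:
                c[1:len(levels)] = -1.0
            assert m.estimate == pytest.approx(float(c @ beta), rel=1e-6)
            assert m.se == pytest.approx(
                float(np.sqrt(c @ cov @ c)), rel=1e-4
            )


class TestBlup:
    def test_toy_blup_pev_and_pairwise_variance(self, toy_oneway):
        fit = fit_lmm(toy_oneway,
                      ModelSpec(response="y", random_terms=("geno",)))
        tab, vbar = blup_pev(fit, "geno")
        blups = dict(zip(tab.level, tab.blup))
        assert blups["A"] == pytest.approx(-3.75, abs=1e-4)
        assert blups["C"] == pytest.approx(3.75, abs=1e-4)
        # prediction-error variance of u_hat - u, Monte-Carlo verified:
        # sigma_g^2 (1 - h) + h^2 Var(mu_hat) contributions give 5.625
        assert tab.pev.iloc[0] == pytest.approx(5.625, abs=1e-3)
        assert vbar == pytest.approx(1.875, abs=1e-4)

    def test_zero_genetic_variance_total_shrinkage(self, toy_oneway):
        data = toy_oneway.assign(y=[10.0, 12, 10, 12, 10, 12])  # no geno signal
        fit = fit_lmm(data, ModelSpec(response="y", random_terms=("geno",)))
        tab, _ = blup_pev(fit, "geno")
        assert np.allclose(tab.blup, 0.0, atol=1e-6)

    def test_blup_order_matches_raw_means_balanced(self):
        rng = np.random.default_rng(3)
        k, n = 8, 4
        g = rng.normal(0, 2.0, k)
        data = pd.DataFrame(
            {
                "geno": np.repeat([f"g{i}" for i in range(k)], n),
                "y": 5.0 + np.repeat(g, n) + rng.normal(0, 1.0, k * n),
            }
        )
        fit = fit_lmm(data, ModelSpec(response="y", random_terms=("geno",)))
        assert fit.varcomp["geno"] > 0
        tab, _ = blup_pev(fit, "geno")
        raw = data.groupby("geno")["y"].mean()
        order_blup = tab.sort_values("blup")["level"].tolist()
        order_raw = raw.sort_values().index.tolist()
        assert order_blup == order_raw


def test_no_residual_df_raises(toy_oneway):
    with pytest.raises(ValueError):
        fit_lmm(toy_oneway.iloc[[0, 2, 4]],
                ModelSpec(response="y", fixed_terms=("geno",)))


def test_term_both_fixed_and_random_rejected():
    with pytest.raises(ValueError):
        ModelSpec(response="y", fixed_terms=("geno",),
                  random_terms=("geno",))
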