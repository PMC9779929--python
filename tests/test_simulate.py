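"""Synthetic program generator: structure, determinism, planted truth."""

import numpy as np
import pandas as pd
import pytest

from stressgain.simulate import (
    CONDITIONS,
    ConfigError,
    ProgramConfig,
    TruthRecord,
    build_program,
    tenure_summary,
)

from conftest import small_config


class TestEntryStructure:
    def test_default_program_reproduces_printed_tenure_table(
        self, default_program
    ):
        plots, _ = default_program
        ts = tenure_summary(plots)
        assert ts["DTSTR"] == {1: 42, 2: 26, 3: 15, 4: 12,
                               5: 6, 6: 3, 7: 5, 8: 3}
        assert sum(ts["DTSTR"].values()) == 112
        commercial = {}
        for cls in ("STRCOM", "CONCOM"):
            for k, v in ts.get(cls, {}).items():
                commercial[k] = commercial.get(k, 0) + v
        assert commercial == {1: 12, 2: 8, 3: 2, 4: 3, 5: 2, 6: 1, 7: 1, 8: 1}
        assert sum(commercial.values()) == 30

    def test_default_met_footprint(self, default_program):
        _, truth = default_program
        met = truth.environments.query("condition == 'MET'")
        assert len(met) == 174
        assert int(met.low_h2.sum()) == 40
        strno = truth.environments.query("condition == 'STRNO'")
        assert int(strno.low_h2.sum()) == 2

    def test_tenure_summary_single_hybrid(self):
        t = pd.DataFrame(
            {"hybrid": ["H1", "H1"], "hybrid_class": ["DTSTR"] * 2,
             "year": [2012, 2012]}
        )
        assert tenure_summary(t) == {"DTSTR": {1: 1}}

    def test_tenure_summary_hand_tally(self):
        t = pd.DataFrame(
            {
                "hybrid": ["A", "A", "A", "B", "B", "C"],
                "hybrid_class": ["DTSTR"] * 5 + ["LOCAL"],
                "year": [2012, 2013, 2013, 2014, 2015, 2012],
            }
        )
        assert tenure_summary(t) == {"DTSTR": {2: 2}, "LOCAL": {1: 1}}


class TestDeterminism:
    def test_same_seed_identical_table(self):
        cfg = small_config()
        p1, _ = build_program(cfg, seed=1234)
        p2, _ = build_program(cfg, seed=1234)
        pd.testing.assert_frame_equal(p1, p2)

    def test_different_seed_same_skeleton_different_noise(self):
        cfg = small_config()
        p1, _ = build_program(cfg, seed=1234)
        p2, _ = build_program(cfg, seed=99)
        key = ["condition", "year", "location", "replicate", "block",
               "hybrid"]
        pd.testing.assert_frame_equal(p1[key], p2[key])
        assert not np.allclose(p1.grain_yield, p2.grain_yield)


class TestPlantedValues:
    def test_noise_free_plots_equal_class_means(self):
        zero = {c: 0.0 for c in CONDITIONS}
        truth = TruthRecord(
            sigma2_G=0, sigma2_GY=0, sigma2_S=0, sigma2_Y=0,
            sigma2_R=0, sigma2_B=0,
            residual_variance_per_condition=dict(zero),
            residual_lognorm_sd=0.0, trend_per_condition=dict(zero),
            low_h2_fraction={},
        )
        cfg = ProgramConfig(
            conditions=("MDS", "STRIN"),
            tenure_distribution={"DTSTR": {1: 4, 8: 2}, "LOCAL": {8: 1}},
            truth=truth,
        )
        plots, _ = build_program(cfg, seed=0)
        expected = (
            plots.condition.map(truth.condition_mean)
            + plots.hybrid_class.map(truth.class_offset)
        )
        assert np.allclose(plots.grain_yield, expected)

    def test_each_hybrid_once_per_replicate(self, small_program):
        plots, _ = small_program
        counts = plots.groupby(
            ["condition", "year", "location", "replicate", "hybrid"]
        ).size()
        assert (counts == 1).all()

    def test_consecutive_tenure_years(self, small_program):
        plots, truth = small_program
        span = plots.groupby("hybrid")["year"].agg(["min", "max", "nunique"])
        merged = span.join(truth.hybrids.set_index("hybrid"))
        assert (merged["min"] == merged["first_year"]).all()
        assert (merged["nunique"] == merged["tenure"]).all()
        assert (merged["max"] - merged["min"] + 1 == merged["tenure"]).all()

    def test_residual_variance_recovered_per_environment(self):
        """With all other variances silenced, the empirical plot variance
        per environment matches its configured sigma2 within 15%."""
        zero = {c: 0.0 for c in CONDITIONS}
        truth = TruthRecord(
            sigma2_G=0, sigma2_GY=0, sigma2_S=0, sigma2_Y=0,
            sigma2_R=0, sigma2_B=0,
            residual_lognorm_sd=0.4,
            trend_per_condition=dict(zero),
            low_h2_fraction={},
        )
        cfg = ProgramConfig(
            conditions=("MDS",),
            tenure_distribution={"DTSTR": {8: 250}},  # 750 plots/environment
            truth=truth,
        )
        plots, pt = build_program(cfg, seed=21)
        plots["environment"] = (
            plots.condition + "|" + plots.location + "|"
            + plots.year.astype(str)
        )
        envvar = pt.environments.set_index("environment")[
            "residual_variance"
        ]
        for env, sub in plots.groupby("environment"):
            resid = sub.grain_yield - sub.hybrid_class.map(truth.class_offset)
            assert len(sub) >= 200
            assert np.var(resid, ddof=1) == pytest.approx(
                envvar[env], rel=0.15
            )

    def test_condition_genetic_correlation_planted(self):
        cfg = small_config()
        _, truth = build_program(cfg, seed=8)
        h = truth.hybrids
        rs = []
        for seed in range(5):
            _, t2 = build_program(cfg, seed=seed)
            rs.append(np.corrcoef(t2.hybrids.g_MDS, t2.hybrids.g_STRIN)[0, 1])
        assert np.mean(rs) == pytest.approx(
            cfg.truth.condition_genetic_corr, abs=0.1
        )
        assert h.g_MDS.std() == pytest.approx(
            np.sqrt(cfg.truth.sigma2_G), rel=0.25
        )


class TestConfigErrors:
    def test_tenure_exceeding_years(self):
        cfg = ProgramConfig(
            n_years=4,
            conditions=("MDS",),
            tenure_distribution={"DTSTR": {8: 2}},
        )
        with pytest.raises(ConfigError):
            build_program(cfg)

    def test_too_few_years(self):
        with pytest.raises(ConfigError):
            ProgramConfig(n_years=1, conditions=("MDS",)).validate()

    def test_single_replicate_rejected(self):
        cfg = ProgramConfig(
            conditions=("MDS",),
            reps_per_condition={"MDS": 1},
            tenure_distribution={"DTSTR": {1: 5}},
        )
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigError):
            TruthRecord(sigma2_G=-1.0).validate()

    def test_entry_classes_consistent_with_tenure(self):
        cfg = small_config()
        totals = cfg.entry_classes
        for cls, dist in cfg.tenure_distribution.items():
            assert totals[cls] == sum(dist.values())
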