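"""Tests for the synthetic labor-cohort generator and association analysis."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from pitosim import cohort as ch
from pitosim import desensitization as ds
from pitosim import schedule
from pitosim.pk_core import MaternalProfile


def small_config(**overrides):
    params = dict(n_cases=4000, oxytocinase_limit_pg_ml=300.0, seed=7)
    params.update(overrides)
    return ch.CohortConfig(**params)


class TestGeneration:
    def test_seeded_runs_bit_reproducible(self):
        c1 = ch.generate_cohort(small_config())
        c2 = ch.generate_cohort(small_config())
        pd.testing.assert_frame_equal(c1.frame, c2.frame)

    def test_growing_n_preserves_earlier_cases(self):
        small = ch.generate_cohort(small_config(n_cases=500)).frame
        large = ch.generate_cohort(small_config(n_cases=1500)).frame
        pd.testing.assert_frame_equal(small, large.iloc[:500].reset_index(drop=True))

    def test_draws_respect_distribution_supports(self):
        df = ch.generate_cohort(small_config()).frame
        cfg = small_config()
        assert df.weight_lb.between(cfg.weight_lb.lower, cfg.weight_lb.upper).all()
        assert df.half_life_min.between(1.0, 6.0).all()
        assert df.ir_mU_min.between(1.0, 36.0).all()
        assert df.duration_min.between(60, 2880).all()

    def test_unexposed_never_cross(self):
        df = ch.generate_cohort(small_config()).frame
        assert not df.loc[~df.exposed, "threshold_crossed"].any()
        assert (df.loc[~df.exposed, "exposure_pg_min_ml"] == 0).all()

    def test_crossing_flags_match_simulated_trajectories(self):
        """Vectorized closed-form flags equal the per-case simulate + assess path."""
        cohort = ch.generate_cohort(
            ch.high_exposure_config(200, 150.0, seed=3)
        )
        cfg = cohort.config
        model = ds.DesensitizationModel(
            oxytocinase_limit_pg_ml=cfg.oxytocinase_limit_pg_ml,
            D_pg_min_per_ml=cfg.D_pg_min_per_ml,
        )
        for case, row in zip(
            cohort.iter_cases(), cohort.frame.itertuples(), strict=True
        ):
            if not case.exposed:
                continue
            series = schedule.simulate(case.schedule, case.profile)
            res = ds.assess_trajectory(series, model)
            assert res.total_exposure_pg_min_ml == pytest.approx(
                row.exposure_pg_min_ml, rel=1e-9, abs=1e-6
            )
            assert res.threshold_crossed == case.threshold_crossed

    def test_limit_above_every_steady_state_gives_null_rr(self):
        cfg = small_config(oxytocinase_limit_pg_ml=1e7, n_cases=20000)
        cohort = ch.generate_cohort(cfg)
        assert cohort.crossing_fraction == 0.0
        res = ch.association(cohort)
        assert abs(math.log(res.relative_risk)) < 3 * res.log_rr_se

    def test_equal_risks_give_null_rr_despite_crossings(self):
        cfg = ch.high_exposure_config(
            20000, 0.0, seed=5, baseline_risk_p0=0.05, above_threshold_risk_p1=0.05
        )
        cohort = ch.generate_cohort(cfg)
        assert cohort.crossing_fraction > 0.1
        res = ch.association(cohort)
        assert abs(math.log(res.relative_risk)) < 3 * res.log_rr_se

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            small_config(baseline_risk_p0=0.5, above_threshold_risk_p1=0.1)
        with pytest.raises(ValueError):
            small_config(n_cases=0)
        with pytest.raises(ValueError):
            small_config(exposure_fraction=1.5)


class TestCrossingMonotonicity:
    def test_fraction_monotone_in_rate_halflife_and_limit(self):
        base = ch.high_exposure_config(20000, 200.0, seed=9)

        def frac(**overrides):
            return ch.generate_cohort(
                dataclasses.replace(base, **overrides)
            ).crossing_fraction

        rates = [
            frac(infusion_rate_mU_min=ch.TruncatedNormal(m, 8.0, 5.0, 48.0))
            for m in (15.0, 25.0, 35.0)
        ]
        assert rates == sorted(rates)
        hls = [
            frac(half_life_min=ch.Uniform(lo, lo + 2.0)) for lo in (1.0, 2.5, 4.0)
        ]
        assert hls == sorted(hls)
        limits = [frac(oxytocinase_limit_pg_ml=L) for L in (0.0, 300.0, 900.0)]
        assert limits == sorted(limits, reverse=True)


class TestCalibration:
    @pytest.mark.parametrize("target", [0.05, 0.2])
    def test_limit_calibration_hits_target_fraction(self, target):
        cfg = ch.high_exposure_config(20000, 0.0, seed=13)
        L = ch.limit_for_crossing_fraction(cfg, target)
        cohort = ch.generate_cohort(
            dataclasses.replace(cfg, oxytocinase_limit_pg_ml=L)
        )
        n_exposed = int(cohort.frame.exposed.sum())
        assert cohort.crossing_fraction == pytest.approx(target, abs=1.5 / n_exposed)

    def test_zero_fraction_means_no_crossings(self):
        cfg = ch.high_exposure_config(5000, 0.0, seed=13)
        L = ch.limit_for_crossing_fraction(cfg, 0.0)
        cohort = ch.generate_cohort(
            dataclasses.replace(cfg, oxytocinase_limit_pg_ml=L)
        )
        assert cohort.crossing_fraction == 0.0

    def test_unattainable_fraction_raises(self):
        cfg = small_config(n_cases=2000)  # general population: ~nobody can cross
        with pytest.raises(ValueError, match="unattainable"):
            ch.limit_for_crossing_fraction(cfg, 0.5)


class TestAssociation:
    def test_symmetric_table_is_null(self):
        res = ch.association_from_counts(5, 45, 5, 45)
        assert res.relative_risk == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_doubling_table(self):
        res = ch.association_from_counts(10, 90, 5, 95)
        assert res.relative_risk == pytest.approx(2.0)
        assert res.rr_ci95[0] < 2.0 < res.rr_ci95[1]

    def test_zero_cell_continuity_corrected(self):
        res = ch.association_from_counts(0, 50, 5, 45)
        assert res.continuity_corrected
        assert res.relative_risk > 0

    def test_requires_both_groups(self):
        with pytest.raises(ValueError):
            ch.association_from_counts(0, 0, 5, 45)

    def test_expected_rr_closed_form(self):
        assert ch.expected_relative_risk(0.0, 0.01, 0.1) == 1.0
        assert ch.expected_relative_risk(1.0, 0.01, 0.1) == pytest.approx(10.0)
        assert ch.expected_relative_risk(0.2, 0.01, 0.1) == pytest.approx(2.8)

    def test_stratified_recovers_risk_ratio(self):
        cfg = ch.high_exposure_config(40000, 0.0, seed=21)
        L = ch.limit_for_crossing_fraction(cfg, 0.2)
        cohort = ch.generate_cohort(
            dataclasses.replace(cfg, oxytocinase_limit_pg_ml=L)
        )
        res = ch.association(cohort)
        p_ratio = cfg.above_threshold_risk_p1 / cfg.baseline_risk_p0
        assert res.crossed_stratum is not None
        lo, hi = res.crossed_stratum.ci95
        assert lo < p_ratio < hi
        lo, hi = res.uncrossed_stratum.ci95
        assert lo < 1.0 < hi


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cohort.yaml"
        path.write_text(
            "n_cases: 100\n"
            "oxytocinase_limit_pg_ml: 250.0\n"
            "seed: 3\n"
            "weight_lb: {kind: truncnorm, mean: 140, sd: 20, lower: 100, upper: 200}\n"
            "half_life_min: {kind: uniform, low: 2, high: 5}\n"
        )
        cfg = ch.load_cohort_config(path)
        assert cfg.n_cases == 100
        assert cfg.weight_lb == ch.TruncatedNormal(140, 20, 100, 200)
        assert cfg.half_life_min == ch.Uniform(2, 5)
        # untouched fields keep defaults
        assert cfg.baseline_risk_p0 == 0.01

    def test_unknown_distribution_kind_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "n_cases: 10\noxytocinase_limit_pg_ml: 0\n"
            "weight_lb: {kind: cauchy, loc: 0}\n"
        )
        with pytest.raises(ValueError, match="cauchy"):
            ch.load_cohort_config(path)

    def test_case_materialization(self):
        cohort = ch.generate_cohort(small_config(n_cases=20))
        cases = list(cohort.iter_cases())
        assert len(cases) == 20
        exposed = [c for c in cases if c.exposed]
        assert exposed, "expected some exposed cases at fraction 0.5"
        c = exposed[0]
        assert isinstance(c.profile, MaternalProfile)
        assert c.schedule is not None
        assert c.schedule.n_cycles == c.duration_min
        unexposed = [c for c in cases if not c.exposed][0]
        assert unexposed.schedule is None

    def test_cases_csv(self, tmp_path):
        cohort = ch.generate_cohort(small_config(n_cases=50))
        path = tmp_path / "cases.csv"
        ch.write_cases_csv(cohort, path)
        df = pd.read_csv(path)
        assert len(df) == 50
        assert {"weight_lb", "exposed", "threshold_crossed", "outcome"} <= set(
            df.columns
        )
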