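import numpy as np
import pandas as pd
import pytest

import melanophot as mp
from melanophot.exceptions import ValidationError
from melanophot.synthetic import (
    MelatoninModelParams,
    PupilModelParams,
    SamplingParams,
    SimConfig,
    generate_study,
    simulate_melatonin_profile,
    simulate_pupil_trace,
    steady_state_diameter,
    study_pupil_table,
    suppression_factor,
)

QUIET = PupilModelParams(noise_sd_mm=0.0, blink_rate_hz=0.0,
                         low_conf_fraction=0.0, subject_sd_mm=0.0)
#: small fast sampling layout for whole-study tests
FAST = SamplingParams(pupil_rate_hz=5.0, n_parts=2, part_minutes=1.0)


class TestPupilTrace:
    def test_noiseless_trace_is_exactly_the_model(self, rng):
        rec = simulate_pupil_trace(30.0, 10.0, 50.0, rng, QUIET)
        assert np.all(
            rec.samples["diameter_mm"] == steady_state_diameter(30.0, QUIET)
        )

    def test_monotone_in_dose(self):
        d = steady_state_diameter(np.array([3.7, 15.0, 70.0, 146.0]), QUIET)
        assert np.all(np.diff(d) < 0)

    def test_blink_contaminated_trace_recovers_model(self):
        """~30% blink-contaminated samples at 20 min × 200 Hz: filtering +
        median binning recovers the model diameter within 0.05 mm."""
        p = PupilModelParams(blink_rate_hz=1.0, blink_duration_s=0.3)
        rng = np.random.default_rng(42)
        rec = simulate_pupil_trace(30.0, 20 * 60.0, 200.0, rng, p)
        contaminated = (rec.samples["confidence"] < 0.6).mean()
        assert 0.2 <= contaminated <= 0.4
        bins = mp.bin_median(mp.filter_samples(rec), bin_minutes=20.0)
        truth = steady_state_diameter(30.0, p)
        assert bins.loc[0, "median_diameter_mm"] == pytest.approx(
            truth, abs=0.05
        )

    def test_blinks_violate_both_filter_clauses(self, rng):
        p = PupilModelParams(blink_rate_hz=1.0, blink_duration_s=0.3,
                             noise_sd_mm=0.0, low_conf_fraction=0.0)
        rec = simulate_pupil_trace(30.0, 60.0, 50.0, rng, p)
        bad = rec.samples[rec.samples["confidence"] < 0.6]
        assert len(bad) > 0
        assert (bad["diameter_mm"] < 2.0).all()

    def test_determinism_under_seed(self):
        a = simulate_pupil_trace(30.0, 5.0, 50.0, np.random.default_rng(7))
        b = simulate_pupil_trace(30.0, 5.0, 50.0, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            PupilModelParams(d_min_mm=8.0, d_max_mm=7.0)
        with pytest.raises(ValidationError):
            PupilModelParams(ar_coef=1.5)
        with pytest.raises(ValidationError):
            simulate_pupil_trace(0.0, 5.0, 50.0, np.random.default_rng(0))


class TestMelatoninProfile:
    def test_half_max_at_s50(self):
        m = MelatoninModelParams(s50=100.0)
        assert suppression_factor(100.0, m) == pytest.approx(0.5)

    def test_no_suppression_in_the_dark_limit(self):
        m = MelatoninModelParams()
        assert suppression_factor(1e-9, m) == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_auc_matches_closed_form(self, rng):
        m = MelatoninModelParams(noise_sd_log=0.0)
        times = np.arange(-5.0, 0.0 + 1e-9, 0.5)
        s = simulate_melatonin_profile(50.0, rng, m, times_h=times)
        auc = mp.melatonin_auc(s, (-4.0, -0.5))
        # ∫ peak/(1+exp(−(t−c)/τ)) dt = peak·τ·log(1+exp((t−c)/τ))
        def F(t):
            return m.baseline_peak_pg_ml * m.rise_tau_h * np.log1p(
                np.exp((t - m.rise_center_h) / m.rise_tau_h)
            )
        exact = (F(-0.5) - F(-4.0)) * suppression_factor(50.0, m)
        assert auc == pytest.approx(exact, rel=0.01)  # trapezoid at h = 0.5

    def test_concentrations_nonnegative_with_noise(self, rng):
        s = simulate_melatonin_profile(50.0, rng)
        assert np.all(s.conc_pg_ml >= 0)


class TestGenerateStudy:
    def test_design_bookkeeping(self):
        cfg = SimConfig(seed=3, sampling=FAST)
        b = generate_study(cfg)
        assert len(b.pupil_recordings) == 144
        assert len(b.melatonin_series) == 144
        assert len(b.ground_truth) == 144
        assert b.assignments["group"].value_counts().tolist() == [18] * 4

    def test_counterbalanced_order(self):
        b = generate_study(SimConfig(seed=3, n_per_group=4, sampling=FAST))
        per_group = b.assignments.groupby("group")["first_condition"]
        for _, counts in per_group.value_counts().groupby(level=0):
            assert sorted(counts.tolist()) == [2, 2]

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=11, n_per_group=2, sampling=FAST)
        a, b = generate_study(cfg), generate_study(cfg)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)
        for ra, rb in zip(a.pupil_recordings, b.pupil_recordings):
            pd.testing.assert_frame_equal(ra.samples, rb.samples)
        for sa, sb in zip(a.melatonin_series, b.melatonin_series):
            assert np.array_equal(sa.conc_pg_ml, sb.conc_pg_ml)

    def test_generated_values_respect_type_invariants(self):
        b = generate_study(SimConfig(seed=5, n_per_group=2, sampling=FAST))
        for rec in b.pupil_recordings[:4]:
            conf = rec.samples["confidence"]
            assert conf.between(0.0, 1.0).all()
            assert rec.samples["t_s"].is_monotonic_increasing

    def test_pupil_table_joins_conditions(self):
        b = generate_study(SimConfig(seed=5, n_per_group=2, sampling=FAST))
        table = study_pupil_table(b)
        assert {"medi_lx", "fraction_valid", "excluded"} <= set(table.columns)
        good = table[~table["excluded"]]["median_diameter_mm"]
        assert good.between(2.0, 10.0).all()

    def test_write_round_trips_text_formats(self, tmp_path):
        b = generate_study(SimConfig(seed=5, n_per_group=1, sampling=FAST))
        b.write(tmp_path)
        for name in ("conditions.csv", "pupil_samples.csv", "melatonin.csv",
                     "ground_truth.csv", "ground_truth_params.json"):
            assert (tmp_path / name).exists()
        pupil = pd.read_csv(tmp_path / "pupil_samples.csv")
        assert {"subject", "session", "timestamp_s", "diameter_3d_mm",
                "confidence"} <= set(pupil.columns)

    def test_lm_sessions_have_larger_pupils(self):
        b = generate_study(SimConfig(seed=9, sampling=FAST))
        gt = b.ground_truth.pivot_table(
            index="subject", columns="session", values="true_diameter_mm"
        )
        assert (gt["LM"] > gt["HM"]).all()


def test_table1_conditions_are_the_printed_grid():
    t = mp.TABLE1_CONDITIONS
    assert len(t) == 8
    assert t["E_mel"].tolist() == [4.91, 20.11, 11.70, 43.51,
                                   27.46, 93.27, 64.17, 193.62]
    # HM arm always carries the higher melanopic irradiance within a group
    wide = t.pivot_table(index="group", columns="arm", values="E_mel")
    assert (wide["HM"] > 3.0 * wide["LM"]).all()
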