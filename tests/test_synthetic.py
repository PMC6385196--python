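"""Ground-truth generators: tachograms, ectopic injection, cohorts."""

import math

import numpy as np
import pytest

from hrvidh import (
    CohortConfig,
    CovariateSpec,
    ModulationProfile,
    StudyConfig,
    filter_ectopic,
    generate_cohort,
    generate_tachogram,
    inject_ectopics,
    simulate_study,
)


def quiet_profile(**kw):
    defaults = dict(base_rr=1000.0, amp_vlf=0.0, amp_lf=0.0, amp_hf=0.0, noise_sd=0.0)
    defaults.update(kw)
    return ModulationProfile(**defaults)


class TestTachogram:
    def test_constant_rate_limit(self):
        s = generate_tachogram(quiet_profile(), duration=300.0, seed=7)
        assert len(s) == 300
        assert np.all(s.rr == 1000.0)
        assert s.time[-1] == pytest.approx(300.0)

    def test_beat_times_cumulate_rr(self):
        p = ModulationProfile(base_rr=900.0, noise_sd=10.0)
        s = generate_tachogram(p, duration=1200.0, seed=5)
        assert np.all(np.diff(s.time) > 0)
        assert s.time[-1] == pytest.approx(np.sum(s.rr) / 1000.0)

    def test_seed_determinism(self):
        p = ModulationProfile(base_rr=900.0, noise_sd=20.0)
        a = generate_tachogram(p, duration=600.0, seed=7)
        b = generate_tachogram(p, duration=600.0, seed=7)
        c = generate_tachogram(p, duration=600.0, seed=8)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.rr, b.rr)
        assert not np.array_equal(a.rr, c.rr)

    def test_nonpositive_rr_rejected(self):
        # slow, oversized VLF swing: the RR trajectory must cross zero and
        # cannot step over the negative region
        p = quiet_profile(base_rr=400.0, amp_vlf=500.0, freq_vlf=0.0035)
        with pytest.raises(ValueError, match="non-positive RR"):
            generate_tachogram(p, duration=600.0, seed=0)

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            generate_tachogram(quiet_profile(), duration=120.0)

    def test_invalid_band_frequency_rejected(self):
        with pytest.raises(ValueError, match="freq_hf"):
            ModulationProfile(freq_hf=0.5)

    def test_trajectory_rises_between_anchors(self):
        p = quiet_profile(
            base_rr=1000.0,
            base_trajectory=(1.0, 1.2, 1.0),
        )
        s = generate_tachogram(p, duration=14400.0, seed=0)
        early = s.rr[s.time < 600].mean()
        middle = s.rr[(s.time > 6900) & (s.time < 7500)].mean()
        assert early == pytest.approx(1000.0)
        assert middle == pytest.approx(1200.0, rel=0.01)


class TestEctopics:
    def test_zero_rate_is_noop(self, noisy_series):
        inj = inject_ectopics(noisy_series, rate=0.0, magnitude=0.3, seed=1)
        np.testing.assert_array_equal(inj.series.rr, noisy_series.rr)
        assert inj.indices.size == 0

    def test_magnitude_at_or_below_rule_threshold_rejected(self, noisy_series):
        with pytest.raises(ValueError, match="magnitude"):
            inject_ectopics(noisy_series, rate=0.05, magnitude=0.2)

    def test_rate_bound(self, noisy_series):
        with pytest.raises(ValueError, match="rate"):
            inject_ectopics(noisy_series, rate=0.5, magnitude=0.3)

    def test_seeded_reproducibility(self, noisy_series):
        a = inject_ectopics(noisy_series, rate=0.05, magnitude=0.3, seed=9)
        b = inject_ectopics(noisy_series, rate=0.05, magnitude=0.3, seed=9)
        np.testing.assert_array_equal(a.indices, b.indices)
        np.testing.assert_array_equal(a.series.rr, b.series.rr)

    def test_flag_count_plausible_for_binomial(self, noisy_series):
        inj = inject_ectopics(noisy_series, rate=0.05, magnitude=0.3, seed=9)
        n = len(noisy_series)
        # 5 sigma band around np = 0.05 n
        sd = math.sqrt(n * 0.05 * 0.95)
        assert abs(inj.indices.size - 0.05 * n) < 5 * sd

    def test_filter_removes_injected_beats(self, series_factory):
        base = series_factory([900.0 + 5 * math.sin(0.1 * k) for k in range(1000)])
        inj = inject_ectopics(base, rate=0.03, magnitude=0.35, seed=4)
        clean = filter_ectopic(inj.series)
        assert set(inj.indices) <= set(clean.removed_indices)

    def test_single_injected_beat_is_removed_exactly(self, series_factory):
        series = series_factory([1000.0] * 50)
        rr = series.rr.copy()
        rr[10] *= 1.3
        corrupted = series_factory(rr)
        clean = filter_ectopic(corrupted)
        assert clean.removed_indices.tolist() == [10]


class TestCohort:
    def test_intercept_only_identity_link_point(self):
        cfg = CohortConfig(
            covariates=(CovariateSpec("x", "constant", (0.0,), beta=5.0),),
            intercept=0.0,
            dispersion=1e-12,
            n_patients=2000,
            seed=3,
        )
        cohort = generate_cohort(cfg)
        assert cohort.table["idh_count"].mean() == pytest.approx(1.0, abs=0.1)

    def test_poisson_limit_mean_two(self):
        cfg = CohortConfig(
            covariates=(),
            intercept=math.log(2.0),
            dispersion=1e-12,
            n_patients=2000,
            seed=11,
        )
        counts = generate_cohort(cfg).table["idh_count"]
        se = math.sqrt(2.0 / 2000)
        assert abs(counts.mean() - 2.0) < 3 * se

    def test_overdispersion_variance_exceeds_mean(self):
        cfg = CohortConfig(
            covariates=(), intercept=math.log(2.0), dispersion=1.0,
            n_patients=5000, seed=2,
        )
        counts = generate_cohort(cfg).table["idh_count"]
        assert counts.var() > counts.mean()

    def test_seed_determinism(self):
        cfg = CohortConfig(
            covariates=(CovariateSpec("ufr", "normal", (2.8, 1.0), beta=0.4),),
            intercept=-0.5, dispersion=0.5, n_patients=100, seed=7,
        )
        a = generate_cohort(cfg).table
        b = generate_cohort(cfg).table
        assert a.equals(b)

    def test_overflow_names_offending_covariate(self):
        cfg = CohortConfig(
            covariates=(CovariateSpec("huge", "normal", (100.0, 1.0), beta=5.0),),
            intercept=0.0, n_patients=10, seed=0,
        )
        with pytest.raises(ValueError, match="huge"):
            generate_cohort(cfg)

    def test_ufr_slope_recovered_at_large_n(self):
        from hrvidh import fit_negative_binomial

        beta = math.log(1.57)  # per-kg ultrafiltration rate ratio
        cfg = CohortConfig(
            covariates=(
                CovariateSpec("ufr", "normal", (2.83, 1.10), beta=beta, clip=(0.0, 6.5)),
            ),
            intercept=-1.0, dispersion=0.5, n_patients=2000, seed=21,
        )
        cohort = generate_cohort(cfg)
        fit = fit_negative_binomial(
            cohort.table["idh_count"].to_numpy(), cohort.table[["ufr"]]
        )
        se = fit.se()["ufr"]
        assert abs(fit.params["ufr"] - beta) < 3 * se


class TestStudy:
    def test_study_shapes_and_determinism(self):
        cfg = StudyConfig(n_patients=12)
        a = simulate_study(cfg, seed=5)
        b = simulate_study(cfg, seed=5)
        assert len(a.profiles) == 12
        assert a.cohort.shape[0] == 12
        assert a.cohort.equals(b.cohort)
        assert a.truth.equals(b.truth)

    def test_truth_deltas_match_band_power_arithmetic(self):
        study = simulate_study(StudyConfig(n_patients=8), seed=1)
        for i, p in enumerate(study.profiles):
            m = p.amp_trajectory["hf"][1]
            expected = 0.5 * p.amp_hf**2 * (m**2 - 1.0)
            assert study.truth["d_hf"].iloc[i] == pytest.approx(expected)

    def test_measured_deltas_track_truth(self):
        import hrvidh.pipeline as pl

        study = simulate_study(StudyConfig(n_patients=20), seed=6)
        feats = pl.study_features(study)
        r = np.corrcoef(feats["d_hf"], study.truth["d_hf"])[0, 1]
        assert r > 0.8
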