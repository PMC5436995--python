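"""Mono-exponential fitting, residence times and the special procedures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from petdosim.reference import Phantom
from petdosim.tac import (
    FitError,
    MonoExpFit,
    ResidenceTimeSet,
    TimeActivityCurve,
    cohort_mean_taus,
    decay_correct,
    decay_uncorrect,
    fit_monoexp,
    marrow_residence_time,
    partition_colon,
    tiac,
)

PHYSICAL_MAX_TAU = 1.1285 / math.log(2)  # = 1.6281 h for Ga-68


def make_tac(t_min, fia, **kw):
    return TimeActivityCurve(subject_id="S01", organ="liver", t_min=t_min, fia=fia, **kw)


class TestDecayCorrection:
    def test_identity_at_time_zero(self, nuclide):
        assert decay_correct(0.37, 0.0, nuclide) == 0.37

    def test_one_half_life_doubles(self, nuclide):
        assert decay_correct(0.5, 67.71, nuclide) == pytest.approx(1.0, rel=1e-12)

    def test_negative_time_rejected(self, nuclide):
        with pytest.raises(ValueError):
            decay_correct(0.1, -1.0, nuclide)

    @given(
        fia=st.floats(1e-6, 1.0),
        t=st.floats(0.0, 240.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, fia, t, nuclide):
        assert decay_uncorrect(decay_correct(fia, t, nuclide), t, nuclide) == pytest.approx(
            fia, rel=1e-12
        )


class TestMonoExpFit:
    def test_exact_recovery_noiseless(self):
        t = np.array([10.0, 60.0, 120.0])
        fia = 0.04 * np.exp(-0.3 * t / 60.0)
        fit = fit_monoexp(make_tac(tuple(t), tuple(fia)))
        assert fit.a0 == pytest.approx(0.04, rel=1e-8)
        assert fit.lambda_bio == pytest.approx(0.3, rel=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_curve(self):
        fit = fit_monoexp(make_tac((10.0, 60.0, 120.0), (0.02, 0.02, 0.02)))
        assert fit.lambda_bio == pytest.approx(0.0, abs=1e-10)
        assert fit.a0 == pytest.approx(0.02, rel=1e-10)
        assert fit.r2 == 1.0

    def test_two_points_interpolate_exactly(self):
        fit = fit_monoexp(make_tac((10.0, 120.0), (0.05, 0.01)))
        assert fit(10.0 / 60.0) == pytest.approx(0.05, rel=1e-10)
        assert fit(2.0) == pytest.approx(0.01, rel=1e-10)
        assert fit.r2 == 1.0

    def test_uptake_phase_negative_rate(self):
        t = np.array([10.0, 60.0, 120.0])
        fia = 1e-4 * np.exp(0.3 * t / 60.0)  # still accumulating
        fit = fit_monoexp(make_tac(tuple(t), tuple(fia)))
        assert fit.lambda_bio == pytest.approx(-0.3, rel=1e-6)

    def test_non_positive_samples_rejected(self):
        with pytest.raises(FitError, match="non-positive"):
            fit_monoexp(make_tac((10.0, 60.0), (0.1, 0.0)))

    def test_uncorrected_curve_rejected(self):
        with pytest.raises(FitError, match="decay-corrected"):
            fit_monoexp(make_tac((10.0, 60.0), (0.1, 0.05), decay_corrected=False))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            make_tac((60.0, 10.0), (0.1, 0.2))


class TestResidenceTime:
    def test_physical_decay_only_gives_maximum(self, nuclide):
        tau = tiac(MonoExpFit(a0=1.0, lambda_bio=0.0, r2=1.0), nuclide)
        assert tau == pytest.approx(PHYSICAL_MAX_TAU, rel=1e-12)

    def test_matched_biological_rate_halves_it(self, nuclide):
        fit = MonoExpFit(a0=1.0, lambda_bio=nuclide.lambda_phys, r2=1.0)
        assert tiac(fit, nuclide) == pytest.approx(PHYSICAL_MAX_TAU / 2, rel=1e-12)

    def test_zero_amplitude(self, nuclide):
        assert tiac(MonoExpFit(a0=0.0, lambda_bio=0.1, r2=1.0), nuclide) == 0.0

    def test_non_integrable_tail_rejected(self, nuclide):
        with pytest.raises(FitError, match="non-integrable"):
            tiac(MonoExpFit(a0=0.1, lambda_bio=-1.5 * nuclide.lambda_phys, r2=1.0), nuclide)

    @given(
        a0=st.floats(1e-4, 0.5),
        lam=st.floats(-0.3, 3.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_closed_form_matches_numerical_integration(self, a0, lam, nuclide):
        """tau equals the integral of the fitted curve times physical decay."""
        fit = MonoExpFit(a0=a0, lambda_bio=lam, r2=1.0)
        horizon = 50 * nuclide.half_life_h
        numeric, _ = quad(
            lambda t: a0 * math.exp(-lam * t) * math.exp(-nuclide.lambda_phys * t),
            0.0,
            horizon,
            limit=500,
        )
        assert tiac(fit, nuclide) == pytest.approx(numeric, rel=1e-6)

    @given(lam=st.floats(-0.3, 3.0), step=st.floats(0.01, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_tau_strictly_decreases_with_clearance_rate(self, lam, step, nuclide):
        t1 = tiac(MonoExpFit(a0=0.1, lambda_bio=lam, r2=1.0), nuclide)
        t2 = tiac(MonoExpFit(a0=0.1, lambda_bio=lam + step, r2=1.0), nuclide)
        assert t2 < t1


class TestMarrowProcedure:
    @staticmethod
    def _voi(organ, mass, a0_per_g, lam, t=(10.0, 60.0, 120.0)):
        fia = tuple(a0_per_g * mass * math.exp(-lam * x / 60.0) for x in t)
        return TimeActivityCurve(
            subject_id="S01", organ=organ, t_min=t, fia=fia, voi_mass_g=mass
        )

    def test_identical_vois_equal_single_voi_value(self, phantom_male, nuclide):
        femora = self._voi("marrow_femora", 60.0, 1e-5, 0.1)
        lumbar = self._voi("marrow_lumbar", 60.0, 1e-5, 0.1)
        tau = marrow_residence_time(femora, lumbar, phantom_male, nuclide)
        per_gram = 1e-5 / (0.1 + nuclide.lambda_phys)
        assert tau == pytest.approx(per_gram * phantom_male.mass("red_marrow"), rel=1e-8)

    def test_arithmetic_mean_of_per_gram_tiacs(self, phantom_male, nuclide):
        femora = self._voi("marrow_femora", 60.0, 2e-5, 0.1)
        lumbar = self._voi("marrow_lumbar", 120.0, 4e-5, 0.1)
        tau = marrow_residence_time(femora, lumbar, phantom_male, nuclide)
        per_gram = 3e-5 / (0.1 + nuclide.lambda_phys)  # mean of 2x and 4x
        assert tau == pytest.approx(per_gram * phantom_male.mass("red_marrow"), rel=1e-8)

    def test_missing_voi_mass_rejected(self, phantom_male, nuclide):
        femora = self._voi("marrow_femora", 60.0, 1e-5, 0.1)
        lumbar = TimeActivityCurve(
            subject_id="S01", organ="marrow_lumbar", t_min=(10.0, 60.0), fia=(1e-3, 9e-4)
        )
        with pytest.raises(ValueError, match="mass"):
            marrow_residence_time(femora, lumbar, phantom_male, nuclide)


class TestColonPartition:
    def test_fixture_masses_split(self, phantom_male):
        tau_uli, tau_lli = partition_colon(0.038, phantom_male)
        assert tau_uli == pytest.approx(0.038 * 220 / 380, rel=1e-12)
        assert tau_lli == pytest.approx(0.038 * 160 / 380, rel=1e-12)
        assert tau_uli + tau_lli == 0.038  # conserved exactly

    def test_equal_masses_split_equally(self):
        phantom = Phantom(
            name="adult_male",
            organ_masses={"uli_wall": 100.0, "lli_wall": 100.0},
            total_body_mass=70000.0,
        )
        assert partition_colon(0.02, phantom) == (0.01, 0.01)

    def test_zero_tau(self, phantom_male):
        assert partition_colon(0.0, phantom_male) == (0.0, 0.0)


class TestCohortStatistics:
    def test_two_subject_mean_and_sd(self):
        a = ResidenceTimeSet(taus={"liver": 0.02}, administered_activity_mbq=200)
        b = ResidenceTimeSet(taus={"liver": 0.04}, administered_activity_mbq=200)
        mean, sd = cohort_mean_taus([a, b])
        assert mean["liver"] == pytest.approx(0.03)
        assert sd["liver"] == pytest.approx(0.0141, abs=1e-4)  # sample SD, n-1

    def test_single_subject_sd_zero_by_convention(self):
        a = ResidenceTimeSet(taus={"liver": 0.02})
        mean, sd = cohort_mean_taus([a])
        assert mean["liver"] == 0.02
        assert sd["liver"] == 0.0

    def test_identical_subjects_have_zero_sd(self):
        subjects = [ResidenceTimeSet(taus={"liver": 0.02, "kidneys": 0.01})] * 5
        _, sd = cohort_mean_taus(subjects)
        assert all(v == 0.0 for v in sd.values())

    def test_mismatched_regions_rejected(self):
        a = ResidenceTimeSet(taus={"liver": 0.02})
        b = ResidenceTimeSet(taus={"kidneys": 0.01})
        with pytest.raises(ValueError, match="mismatched"):
            cohort_mean_taus([a, b])

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ResidenceTimeSet(taus={"liver": -0.01})
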