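"""Closed-form kinetic model: sham term, cluster focus probability, totals."""

import math

import numpy as np
import pytest

from foci_kinetics import (
    ClusterSpectrum,
    KineticsParams,
    ModelOptions,
    TrackParams,
    cluster_focus_prob,
    persistent_fraction_from_mean,
    persistent_mean_from_fraction,
    radiation_mean,
    reparameterize,
    sham_mean,
    total_mean,
)
from foci_kinetics.kinetics import ParameterError

FRACTION = ModelOptions()
MEAN_NUMBER = ModelOptions(parameterization="mean-number")


def make_params(**kw):
    base = dict(n_background=0.24, n_sham=0.26, beta0=0.3, beta1=0.27, beta2=0.01)
    base.update(kw)
    return KineticsParams(**base)


class TestShamMean:
    def test_reference_time_and_frozen_rate(self):
        p = make_params()
        assert sham_mean(0.5, p) == pytest.approx(0.24 + 0.26)
        p0 = make_params(beta0=0.0)
        assert sham_mean(24.0, p0) == pytest.approx(0.24 + 0.26)

    def test_against_scalar_reimplementation(self):
        p = make_params()
        # independent scalar evaluation of n_b + n_s e^{-beta0 (t - t_ref)}
        expected = 0.24 + 0.26 * math.exp(-0.3 * 23.5)
        assert sham_mean(24.0, p) == pytest.approx(expected, rel=1e-14)

    def test_time_before_reference_rejected(self):
        with pytest.raises(ParameterError):
            sham_mean(0.25, make_params())


class TestClusterFocusProb:
    def setup_method(self):
        self.params = make_params(
            tracks={"q": TrackParams(0.8, p_persistent=0.2)}
        )

    def test_reference_time_depends_only_on_track_yield(self):
        for n in (1, 2, 5):
            expected = 1.0 - math.exp(-n * 0.8)
            assert cluster_focus_prob(0.5, n, self.params, "q") == pytest.approx(
                expected
            )

    def test_zero_yield_gives_zero(self):
        p = make_params(tracks={"q": TrackParams(0.0, p_persistent=0.2)})
        assert cluster_focus_prob(8.0, 3, p, "q") == 0.0

    def test_long_time_limit_with_frozen_persistent_foci(self):
        p = make_params(beta2=0.0, tracks={"q": TrackParams(0.8, p_persistent=0.2)})
        limit = 1.0 - math.exp(-2 * 0.8 * 0.2)
        assert cluster_focus_prob(1e6, 2, p, "q") == pytest.approx(limit, abs=1e-12)

    def test_parameterizations_agree_on_random_grid(self, rng):
        for _ in range(300):
            n_track = rng.uniform(0, 3)
            p_pers = rng.uniform(0, 1)
            params = make_params(
                beta1=rng.uniform(0, 2),
                beta2=rng.uniform(0, 2),
                tracks={
                    "q": TrackParams(
                        n_track,
                        p_persistent=p_pers,
                        persistent_mean=n_track * p_pers,
                    )
                },
            )
            t = rng.uniform(0.5, 48)
            n_i = int(rng.integers(1, 8))
            a = cluster_focus_prob(t, n_i, params, "q", FRACTION)
            b = cluster_focus_prob(t, n_i, params, "q", MEAN_NUMBER)
            assert abs(a - b) <= 1e-12

    def test_bounded_and_non_increasing(self):
        t = np.linspace(0.5, 48, 200)
        vals = cluster_focus_prob(t, 3, self.params, "q")
        assert np.all((vals >= 0) & (vals < 1))
        assert np.all(np.diff(vals) <= 1e-15)

    def test_matches_poisson_thinning_enumeration(self):
        # oracle: void probability of a thinned Poisson count, by direct
        # summation of the Poisson mass up to negligible truncation error
        n_i, t = 3, 6.0
        tp = self.params.tracks["q"]
        lam = n_i * tp.n_track
        d = t - 0.5
        s = (1 - 0.2) * math.exp(-0.27 * d) + 0.2 * math.exp(-0.01 * d)
        p_no_focus = sum(
            math.exp(-lam) * lam**k / math.factorial(k) * (1 - s) ** k
            for k in range(80)
        )
        assert cluster_focus_prob(t, n_i, self.params, "q") == pytest.approx(
            1 - p_no_focus, abs=1e-12
        )

    def test_mean_exceeding_yield_rejected_when_checked(self):
        p = make_params(tracks={"q": TrackParams(0.5, persistent_mean=0.9)})
        with pytest.raises(ParameterError):
            cluster_focus_prob(2.0, 1, p, "q", MEAN_NUMBER)
        # the unchecked path (used inside box-bounded optimisation) evaluates
        assert 0 < cluster_focus_prob(2.0, 1, p, "q", MEAN_NUMBER, check=False) < 1


class TestRadiationAndTotalMean:
    def test_empty_spectrum_gives_zero(self):
        spectrum = ClusterSpectrum("q", {}, n_nuclei=1)
        p = make_params(tracks={"q": TrackParams(0.8, p_persistent=0.2)})
        assert radiation_mean(4.0, spectrum, p) == 0.0

    def test_small_yield_first_order(self):
        spectrum = ClusterSpectrum("q", {1: 5.0}, n_nuclei=1)
        p = make_params(tracks={"q": TrackParams(1e-4, p_persistent=0.2)})
        val = radiation_mean(0.5, spectrum, p)
        assert val <= 5 * 1e-4
        assert val == pytest.approx(5 * 1e-4, rel=1e-3)

    def test_total_reduces_to_sham_without_radiation(self):
        spectrum = ClusterSpectrum("q", {1: 3.0}, n_nuclei=1)
        p = make_params(tracks={"q": TrackParams(0.0, p_persistent=0.0)})
        t = np.array([0.5, 4.0, 24.0])
        assert np.allclose(total_mean(t, "q", spectrum, p), sham_mean(t, p))

    def test_total_monotone_non_increasing(self):
        spectrum = ClusterSpectrum("q", {1: 3.0, 2: 0.5, 3: 0.1}, n_nuclei=1)
        p = make_params(tracks={"q": TrackParams(1.2, p_persistent=0.15)})
        t = np.linspace(0.5, 48, 300)
        vals = np.asarray(total_mean(t, "q", spectrum, p))
        assert np.all(np.diff(vals) <= 1e-12)

    def test_reference_time_identity(self):
        spectrum = ClusterSpectrum("q", {1: 3.0, 2: 0.5}, n_nuclei=1)
        p = make_params(tracks={"q": TrackParams(0.9, p_persistent=0.1)})
        expected = (
            0.24 + 0.26
            + 3.0 * (1 - math.exp(-0.9))
            + 0.5 * (1 - math.exp(-2 * 0.9))
        )
        assert total_mean(0.5, "q", spectrum, p) == pytest.approx(expected, abs=1e-14)

    def test_plateau_equals_closed_form_limit(self):
        spectrum = ClusterSpectrum("q", {1: 3.0, 2: 0.5}, n_nuclei=1)
        p = make_params(
            beta2=0.0, tracks={"q": TrackParams(0.9, p_persistent=0.1)}
        )
        limit = 0.24 + sum(
            k * (1 - math.exp(-n * 0.9 * 0.1)) for n, k in spectrum.k_bar.items()
        )
        assert total_mean(1e6, "q", spectrum, p) == pytest.approx(limit, abs=1e-10)

    def test_quality_mismatch_rejected(self):
        spectrum = ClusterSpectrum("other", {1: 3.0}, n_nuclei=1)
        p = make_params(tracks={"q": TrackParams(0.9, p_persistent=0.1)})
        with pytest.raises(ParameterError):
            total_mean(1.0, "q", spectrum, p)


class TestReparameterize:
    @pytest.mark.parametrize(
        "n_track, p, expected_pbar",
        [(0.37, 0.17, 0.06), (0.63, 0.10, 0.06), (1.08, 0.11, 0.12)],
    )
    def test_persistent_mean_identity(self, n_track, p, expected_pbar):
        assert round(persistent_mean_from_fraction(n_track, p), 2) == expected_pbar

    def test_persistent_fraction_identity(self):
        assert round(persistent_fraction_from_mean(1.09, 0.23), 2) == 0.21

    def test_zero_fraction_gives_zero_mean(self):
        assert persistent_mean_from_fraction(1.0, 0.0) == 0.0

    def test_zero_yield_with_positive_mean_rejected(self):
        with pytest.raises(ParameterError):
            persistent_fraction_from_mean(0.0, 0.1)

    def test_round_trip_over_params(self, rng):
        for _ in range(50):
            n_track = rng.uniform(0.01, 3)
            p_pers = rng.uniform(0, 1)
            params = make_params(
                tracks={"q": TrackParams(n_track, p_persistent=p_pers)}
            )
            back = reparameterize(
                reparameterize(params, "to-mean"), "to-fraction"
            )
            assert back.tracks["q"].p_persistent == pytest.approx(
                p_pers, abs=1e-14
            )
            assert back.tracks["q"].n_track == n_track
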