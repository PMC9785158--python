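import numpy as np
import pytest

from foci_kinetics import (
    ClusterSpectrum,
    FociDataset,
    ModelOptions,
    reference_params,
    sham_mean,
    total_mean,
)

QUALITIES = ["p_3MeV", "a_20MeV", "a_10MeV", "a_8MeV"]
TIMES = np.array([0.5, 2.0, 4.0, 8.0, 24.0])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def ref_params():
    return reference_params()


@pytest.fixture
def fixed_spectra():
    """Fixed, analytic cluster spectra — no Monte Carlo noise in fit tests."""
    k_bar = {1: 3.0, 2: 0.6, 3: 0.15, 4: 0.03}
    return {
        q: ClusterSpectrum(quality=q, k_bar=dict(k_bar), n_nuclei=1000, seed=0)
        for q in QUALITIES
    }


def closed_form_datasets(params, spectra, sd=0.05, qualities=None, times=TIMES):
    """Noise-free datasets whose means are exactly the model's closed form."""
    qualities = qualities or QUALITIES
    out = []
    for q in qualities:
        mean = np.asarray(total_mean(times, q, spectra[q], params))
        out.append(
            FociDataset(q, times.copy(), mean, np.full_like(times, sd))
        )
    sham = np.asarray(sham_mean(times, params))
    out.append(FociDataset("sham", times.copy(), sham, np.full_like(times, sd)))
    return out


@pytest.fixture
def noise_free_datasets(ref_params, fixed_spectra):
    return closed_form_datasets(ref_params, fixed_spectra)
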