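import pytest

from wabkit.banddecomp import CLASS_ORDER
from wabkit.preprocess import (
    WAB_REGION,
    extract_region,
    fit_background,
    normalize_area,
    subtract_background,
)
from wabkit.synthetic_data import SyntheticTruth, default_grid, generate_spectrum

#: Seven-band truth with every population comfortably above 0.05.
SEVEN_POPS = {
    "W0a": 0.08, "W0b": 0.10, "W1": 0.12, "W2a": 0.25,
    "W2b": 0.18, "W3": 0.15, "W4": 0.12,
}

#: Five-mandatory-band truth (optional duplication bands absent).
FIVE_POPS = {
    "W0a": 0.0, "W0b": 0.15, "W1": 0.12, "W2a": 0.35,
    "W2b": 0.0, "W3": 0.20, "W4": 0.18,
}


def make_truth(pops, noise_sd=0.0, seed=0, **kw):
    full = {name: pops.get(name, 0.0) for name in CLASS_ORDER}
    return SyntheticTruth(populations=full, noise_sd=noise_sd, seed=seed, **kw)


def prep_band(spectrum):
    """Background-subtract, crop to the WAB region, area-normalize."""
    bg = fit_background(spectrum)
    corrected = subtract_background(spectrum, bg)
    return normalize_area(extract_region(corrected, WAB_REGION), WAB_REGION)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def seven_band_noiseless():
    return generate_spectrum(make_truth(SEVEN_POPS))


@pytest.fixture(scope="session")
def seven_band_prepped(seven_band_noiseless):
    return prep_band(seven_band_noiseless)
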