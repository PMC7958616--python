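import math

import numpy as np
import pytest

from conftest import SEVEN_POPS, make_truth, prep_band
from wabkit.banddecomp import (
    CLASS_ORDER,
    MANDATORY_CLASSES,
    TAXONOMY,
    Decomposition,
    GaussianComponent,
    aggregate_replicates,
    assign_band,
    fit_fixed_set,
)
from wabkit.errors import RangeError, UsageError
from wabkit.gaussians import gaussian
from wabkit.preprocess import WAB_REGION, BackgroundModel, extract_region, normalize_area
from wabkit.spectra_io import Spectrum
from wabkit.synthetic_data import DEFAULT_CENTERS, default_grid, generate_spectrum


def _normalized(y, grid=None):
    grid = default_grid() if grid is None else grid
    return normalize_area(extract_region(Spectrum(grid, y), WAB_REGION), WAB_REGION)


NO_BACKGROUND = BackgroundModel(0.0, 2900.0, 300.0, 0.0)


class TestTaxonomy:
    def test_windows(self):
        expected = {
            "W0a": (2000, 2010), "W0b": (2015, 2035), "W1": (2045, 2065),
            "W2a": (2080, 2120), "W2b": (2120, 2160), "W3": (2170, 2200),
            "W4": (2230, 2270),
        }
        for name, (lo, hi) in expected.items():
            assert (TAXONOMY[name].window.lo, TAXONOMY[name].window.hi) == (lo, hi)

    def test_mandatory_set(self):
        assert MANDATORY_CLASSES == ("W0b", "W1", "W2a", "W3", "W4")


class TestAssignBand:
    @pytest.mark.parametrize(
        "center,name,in_window",
        [
            (2255.0, "W4", True),  # cubic-ice maximum
            (2100.0, "W2a", True),
            (2120.0, "W2a", True),  # shared boundary -> lower class
            (2040.0, "W0b", False),  # gap midpoint, tie toward lower class
            (2070.0, "W1", False),  # nearer to W1 (2065) than W2a (2080)
            (2300.0, "W4", False),  # above all windows
            (2000.0, "W0a", True),
        ],
    )
    def test_assignment(self, center, name, in_window):
        assert assign_band(center) == (name, in_window)

    @pytest.mark.parametrize("center", [1999.0, 2501.0])
    def test_out_of_range(self, center):
        with pytest.raises(RangeError):
            assign_band(center)


class TestFitFixedSet:
    def test_single_component_identity(self):
        grid = default_grid()
        band = _normalized(gaussian(grid, 2100, 60, 1.0))
        d = fit_fixed_set(band, ["W2a"])
        assert d.component("W2a").center == pytest.approx(2100.0, abs=1e-6)
        assert d.populations["W2a"] == pytest.approx(1.0, abs=1e-9)

    def test_two_component_area_ratio(self):
        # equal FWHM, amplitudes 2:1 -> analytic areas 2:1 -> populations 2/3, 1/3
        grid = default_grid()
        band = _normalized(gaussian(grid, 2100, 60, 2.0) + gaussian(grid, 2250, 60, 1.0))
        d = fit_fixed_set(band, ["W2a", "W4"])
        assert d.populations["W2a"] == pytest.approx(2 / 3, abs=1e-6)
        assert d.populations["W4"] == pytest.approx(1 / 3, abs=1e-6)

    def test_seven_window_midpoints_equal_areas(self):
        truth = make_truth(
            {n: 1 / 7 for n in CLASS_ORDER},
            fwhms={n: 50.0 for n in CLASS_ORDER},
            background=NO_BACKGROUND,
        )
        band = _normalized(generate_spectrum(truth).absorbance)
        d = fit_fixed_set(band, CLASS_ORDER)
        for name in CLASS_ORDER:
            assert d.populations[name] == pytest.approx(1 / 7, abs=1e-4)

    def test_noiseless_recovery_well_separated(self):
        # pairwise center separations >= 40 cm-1
        pops = {"W0a": 0.15, "W1": 0.15, "W2a": 0.2, "W2b": 0.15, "W3": 0.2, "W4": 0.15}
        truth = make_truth(pops, background=NO_BACKGROUND)
        band = _normalized(generate_spectrum(truth).absorbance)
        d = fit_fixed_set(band, list(pops))
        for name, p in pops.items():
            assert d.populations[name] == pytest.approx(p, abs=1e-4)
            assert d.component(name).center == pytest.approx(DEFAULT_CENTERS[name], abs=0.1)

    def test_populations_sum_to_one(self, seven_band_prepped):
        d = fit_fixed_set(seven_band_prepped, CLASS_ORDER)
        assert sum(d.populations.values()) == pytest.approx(1.0, abs=1e-9)

    def test_nested_rss_monotone_under_warm_start(self, seven_band_prepped):
        small = fit_fixed_set(seven_band_prepped, MANDATORY_CLASSES)
        large = fit_fixed_set(seven_band_prepped, CLASS_ORDER, warm_from=small)
        assert large.rss <= small.rss + 1e-12

    def test_deterministic_bit_identical(self):
        truth = make_truth(SEVEN_POPS, noise_sd=0.003, seed=11)
        band = prep_band(generate_spectrum(truth))
        d1 = fit_fixed_set(band, CLASS_ORDER)
        d2 = fit_fixed_set(band, CLASS_ORDER)
        assert d1 == d2

    def test_centers_respect_windows(self):
        truth = make_truth(SEVEN_POPS, noise_sd=0.003, seed=7)
        band = prep_band(generate_spectrum(truth))
        d = fit_fixed_set(band, CLASS_ORDER)
        for c in d.components:
            win = TAXONOMY[c.class_name].window
            assert win.lo <= c.center <= win.hi
            assert 20.0 <= c.fwhm <= 200.0
            assert c.amplitude >= 0

    def test_spectrum_not_covering_windows_is_range_error(self):
        grid = 2050.0 + np.arange(400.0)
        s = Spectrum(grid, np.full(400, 0.1))
        with pytest.raises(RangeError):
            fit_fixed_set(s, CLASS_ORDER)

    def test_empty_class_set_is_usage_error(self, seven_band_prepped):
        with pytest.raises(UsageError):
            fit_fixed_set(seven_band_prepped, [])

    def test_json_serialization_fields(self, seven_band_prepped):
        import json

        d = fit_fixed_set(seven_band_prepped, MANDATORY_CLASSES)
        doc = json.loads(d.to_json())
        assert set(doc) >= {"components", "populations", "rss", "bic", "n_points"}
        assert len(doc["components"]) == 5


def _decomp(sample_id, pops, centers):
    comps = tuple(
        GaussianComponent(n, centers[n], 50.0, 1.0) for n in pops
    )
    return Decomposition(
        components=comps, populations=dict(pops), rss=0.0, n_points=100,
        bic=0.0, sample_id=sample_id,
    )


class TestAggregateReplicates:
    def test_two_replicate_statistics(self):
        a = _decomp("s", {"W2a": 0.5, "W4": 0.5}, {"W2a": 2100.0, "W4": 2250.0})
        b = _decomp("s", {"W2a": 0.3, "W4": 0.7}, {"W2a": 2102.0, "W4": 2252.0})
        out = aggregate_replicates([a, b])
        assert out.classes["W2a"].mean_population == pytest.approx(0.4)
        assert out.classes["W4"].mean_population == pytest.approx(0.6)
        # sample SD of {0.5, 0.3} = 0.1414...
        assert out.classes["W2a"].sd_population == pytest.approx(math.sqrt(0.02), rel=1e-9)
        assert out.classes["W2a"].mean_center == pytest.approx(2101.0)

    def test_single_replicate_sd_zero(self):
        a = _decomp("s", {"W2a": 1.0}, {"W2a": 2100.0})
        out = aggregate_replicates([a])
        assert out.classes["W2a"].sd_population == 0.0
        assert out.classes["W2a"].sd_center == 0.0
        assert out.n_replicates == 1

    def test_absent_class_counts_zero_population_but_not_center(self):
        reps = [
            _decomp("s", {"W2a": 0.7, "W2b": 0.3}, {"W2a": 2100.0, "W2b": 2140.0}),
            _decomp("s", {"W2a": 0.6, "W2b": 0.4}, {"W2a": 2100.0, "W2b": 2150.0}),
            _decomp("s", {"W2a": 1.0}, {"W2a": 2100.0}),
        ]
        out = aggregate_replicates(reps)
        assert out.classes["W2b"].mean_population == pytest.approx((0.3 + 0.4 + 0.0) / 3)
        assert out.classes["W2b"].mean_center == pytest.approx(2145.0)  # over the two present
        assert out.classes["W2b"].n_present == 2

    def test_mixed_sample_ids_rejected(self):
        a = _decomp("s1", {"W2a": 1.0}, {"W2a": 2100.0})
        b = _decomp("s2", {"W2a": 1.0}, {"W2a": 2100.0})
        with pytest.raises(UsageError):
            aggregate_replicates([a, b])

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            aggregate_replicates([])
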