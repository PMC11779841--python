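"""Spectral integration, density calibration and component quantification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from biofilmnmr import quant
from biofilmnmr.errors import ComputationError, InputError
from biofilmnmr.quant import (
    RegionSet,
    carbon_biomass_density,
    component_quant,
    degradation_observations,
    group_components,
    integrate_region,
    mobile_fraction,
    track_peak_intensity,
)
from biofilmnmr.spectra import Spectrum1D
from biofilmnmr.synthetic import (
    build_scenario,
    emit_component_volumes,
    ground_truth,
    render_spectrum,
)

from conftest import lorentzian_spectrum


def lorentzian_cdf_mass(center, hwhm, lo, hi):
    """Closed-form fraction of a unit Lorentzian inside [lo, hi]."""
    return (np.arctan((hi - center) / hwhm) - np.arctan((lo - center) / hwhm)) / np.pi


class TestIntegrateRegion:
    def test_zero_spectrum_integrates_to_zero(self):
        s = Spectrum1D(np.linspace(200, 0, 100), np.zeros(100), 1.0, 1, "qDP", 1)
        assert integrate_region(s, (74, 105)) == 0.0

    def test_unit_lorentzian_mass_matches_arctan_oracle(self):
        s = lorentzian_spectrum(center=90.0, hwhm=0.5)
        got = integrate_region(s, (74, 105))
        oracle = lorentzian_cdf_mass(90.0, 0.5, 74.0, 105.0)
        assert oracle == pytest.approx(0.97945, abs=5e-5)  # frozen from the arctan CDF
        assert got == pytest.approx(oracle, abs=1e-4)

    def test_adjacent_intervals_add_exactly(self):
        s = lorentzian_spectrum(center=90.0, hwhm=0.5)
        whole = integrate_region(s, (74, 105))
        parts = integrate_region(s, (74, 90)) + integrate_region(s, (90, 105))
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_axis_direction_invariance(self):
        up = lorentzian_spectrum(descending=False)
        down = lorentzian_spectrum(descending=True)
        assert integrate_region(up, (74, 105)) == pytest.approx(
            integrate_region(down, (74, 105)), rel=1e-9
        )

    def test_zero_overlap_rejected(self):
        s = lorentzian_spectrum()
        with pytest.raises(InputError):
            integrate_region(s, (300, 400))
        with pytest.raises(InputError):
            integrate_region(s, (50, 50))


class TestCarbonBiomassDensity:
    def test_density_arithmetic(self):
        # integral 96 over 30 mg and 64 scans → 0.05
        ppm = np.linspace(0, 96, 2)
        s = Spectrum1D(ppm, np.ones(2), sample_mass_mg=30.0, n_scans=64, mode="qDP", day=1)
        assert carbon_biomass_density(s) == pytest.approx(96.0 / (30.0 * 64.0), rel=1e-12)

    def test_joint_scaling_of_intensity_and_scans_is_invariant(self):
        s = lorentzian_spectrum(n_scans=8)
        scaled = Spectrum1D(
            s.ppm, s.intensity * 16.0, s.sample_mass_mg, s.n_scans * 16, s.mode, s.day
        )
        assert carbon_biomass_density(scaled) == pytest.approx(
            carbon_biomass_density(s), rel=1e-12
        )

    def test_non_quantitative_mode_warns(self):
        s = lorentzian_spectrum(mode="DP2s")
        with pytest.warns(UserWarning, match="not quantitative"):
            carbon_biomass_density(s)

    def test_relative_trajectory_recovers_ground_truth(self, default_scenario):
        sc = default_scenario
        truth = ground_truth(sc)
        specs = [render_spectrum(sc, d, "qDP") for d in sc.days]
        dens = {s.day: carbon_biomass_density(s) for s in specs}
        ref = dens[2]
        for d in sc.days:
            expected = truth.total_biomass_by_day[d] / truth.total_biomass_by_day[2]
            assert dens[d] / ref == pytest.approx(expected, abs=0.01)


class TestMobileFraction:
    def test_identical_spectra_give_unity(self):
        q = lorentzian_spectrum()
        m = lorentzian_spectrum(mode="DP2s")
        assert mobile_fraction(m, q) == pytest.approx(1.0, rel=1e-12)

    def test_two_phase_forward_model_recovers_known_fraction(self, two_phase_scenario):
        # true mobile fraction 0.91 with T1 0.5 s (mobile) vs 20 s (rigid):
        # the residual-saturation bias stays below 0.01
        q = render_spectrum(two_phase_scenario, 1, "qDP")
        m = render_spectrum(two_phase_scenario, 1, "DP2s")
        assert mobile_fraction(m, q) == pytest.approx(0.91, abs=0.01)

    def test_noise_driven_excess_is_clamped_with_warning(self):
        q = lorentzian_spectrum()
        m = Spectrum1D(q.ppm, q.intensity * 1.03, q.sample_mass_mg, q.n_scans, "DP2s", q.day)
        with pytest.warns(UserWarning, match="clamped"):
            assert mobile_fraction(m, q) == 1.0

    def test_monotone_in_true_mobile_share(self):
        """Estimated fraction increases with the configured mobile share."""
        estimates = []
        for mf in (0.2, 0.5, 0.8, 0.95):
            cfg = {
                "components": {
                    "x": {
                        "peaks": [(90.0, 0.6, 1.0)],
                        "biomass_by_day": {1: 1.0},
                        "mobile_fraction_by_day": {1: mf},
                        "t1_mobile_s": 0.5,
                        "t1_rigid_s": 20.0,
                    }
                },
                "days": [1],
            }
            sc = build_scenario(cfg, seed=0)
            estimates.append(
                mobile_fraction(render_spectrum(sc, 1, "DP2s"), render_spectrum(sc, 1, "qDP"))
            )
        assert np.all(np.diff(estimates) > 0)

    def test_day_mismatch_rejected(self):
        q = lorentzian_spectrum(day=1)
        m = lorentzian_spectrum(mode="DP2s", day=2)
        with pytest.raises(InputError):
            mobile_fraction(m, q)

    def test_zero_qdp_density_rejected(self):
        ppm = np.linspace(200, 0, 50)
        q = Spectrum1D(ppm, np.zeros(50), 1.0, 1, "qDP", 1)
        m = Spectrum1D(ppm, np.ones(50), 1.0, 1, "DP2s", 1)
        with pytest.raises(ComputationError):
            mobile_fraction(m, q)


class TestComponentQuant:
    def test_recovers_ground_truth_shape(self, default_scenario):
        sc = default_scenario
        truth = ground_truth(sc)
        specs = [render_spectrum(sc, d, m) for d in sc.days for m in ("qDP", "DP2s")]
        table = component_quant(specs)
        for cls in ("carbohydrate", "protein"):
            est = (
                table[table["component"] == cls]
                .set_index("day")["relative_density"]
                .sort_index()
            )
            ref = truth.biomass_by_day[cls][2]
            true = np.array([truth.biomass_by_day[cls][d] / ref for d in sc.days])
            r, _ = pearsonr(est.to_numpy(), true)
            assert r >= 0.99
            assert est.loc[2] == 1.0  # reference day exactly 1

    def test_empty_region_list_rejected(self):
        with pytest.raises(InputError):
            RegionSet({"carbohydrate": []})

    def test_overlapping_intervals_within_class_rejected(self):
        with pytest.raises(InputError):
            RegionSet({"protein": [(10, 30), (25, 48)]})

    def test_missing_mode_pairing_reported(self, default_scenario):
        specs = [render_spectrum(default_scenario, d, "qDP") for d in default_scenario.days]
        with pytest.raises(InputError, match="DP2s"):
            component_quant(specs)


class TestTrackPeakIntensity:
    def _series(self, heights):
        out = []
        for day, h in enumerate(heights, start=1):
            out.append(lorentzian_spectrum(center=65.2, hwhm=0.3, area=h, day=day))
        return out

    def test_presence_then_absence(self):
        tracked = track_peak_intensity(self._series([1.0, 0.5, 1e-6]), 65.2, 1.0)
        assert tracked.loc[1] == pytest.approx(1.0)
        assert tracked.loc[3] < 1e-4

    def test_constant_peak_is_all_ones(self):
        tracked = track_peak_intensity(self._series([2.0, 2.0, 2.0]), 65.2, 1.0)
        assert np.allclose(tracked.to_numpy(), 1.0)

    def test_integral_mode_matches_height_mode_for_fixed_shape(self):
        spectra = self._series([1.0, 0.25])
        by_h = track_peak_intensity(spectra, 65.2, 1.0, method="height")
        by_i = track_peak_intensity(spectra, 65.2, 1.0, method="integral")
        assert np.allclose(by_h.to_numpy(), by_i.to_numpy(), rtol=1e-6)

    def test_glycerol_reference_centers_are_shipped(self):
        assert quant.GLYCEROL_PEAKS_PPM == (65.187, 72.775)

    def test_window_outside_axis_rejected(self):
        with pytest.raises(InputError):
            track_peak_intensity(self._series([1.0]), 300.0, 1.0)
        with pytest.raises(InputError):
            track_peak_intensity(self._series([1.0]), 65.2, 0.0)


class TestGroupComponents:
    def test_single_category_is_hundred_percent(self):
        volumes = pd.DataFrame(
            {"peak": ["a", "b"], "day": [2, 2], "volume": [3.0, 7.0]}
        )
        table = group_components(volumes, {"a": "proteins", "b": "proteins"})
        assert table["proportion"].iloc[0] == pytest.approx(100.0, abs=1e-9)
        assert table["quantity"].iloc[0] == pytest.approx(100.0)

    def test_proportions_sum_to_hundred_on_random_tables(self):
        rng = np.random.default_rng(5)
        peaks = [f"p{i}" for i in range(12)]
        cats = dict(zip(peaks, rng.choice(quant.COMPONENT_CATEGORIES, size=12)))
        cats["p0"] = "proteins"
        rows = [
            {"peak": p, "day": d, "volume": rng.uniform(0.1, 5.0)}
            for p in peaks
            for d in (1, 2, 3)
        ]
        table = group_components(pd.DataFrame(rows), cats)
        sums = table.groupby("day")["proportion"].sum()
        assert np.allclose(sums.to_numpy(), 100.0, atol=1e-9)

    def test_unmapped_peaks_fall_into_unknown(self):
        volumes = pd.DataFrame(
            {"peak": ["a", "z"], "day": [2, 2], "volume": [1.0, 1.0]}
        )
        table = group_components(volumes, {"a": "proteins"})
        assert set(table["category"]) == {"proteins", "unknown"}

    def test_duplicate_peak_identifiers_rejected(self):
        volumes = pd.DataFrame(
            {"peak": ["a", "a"], "day": [2, 2], "volume": [1.0, 1.0]}
        )
        with pytest.raises(InputError, match="duplicated"):
            group_components(volumes, {"a": "proteins"})

    def test_lipid_spike_ratio_preserved(self, default_scenario):
        # the day-3 → day-4 aliphatic surge (0.2 → 1.8) survives grouping
        volumes, cmap = emit_component_volumes(default_scenario)
        table = group_components(volumes, cmap)
        lip = table[table["category"] == "lipids/biosurfactants"].set_index("day")
        assert lip.loc[4, "quantity"] / lip.loc[3, "quantity"] == pytest.approx(9.0, rel=1e-9)

    def test_degradation_observations_match_configured_declines(self, default_scenario):
        volumes, cmap = emit_component_volumes(default_scenario)
        table = group_components(volumes, cmap)
        dp1, dp2, dc1, dc2 = degradation_observations(table)
        assert (dp1, dp2) == pytest.approx((49.28, 31.31), abs=1e-9)
        assert (dc1, dc2) == pytest.approx((14.18, 33.43), abs=1e-9)
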