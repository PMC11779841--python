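"""Scenario construction, spectrum rendering and dataset emission."""

import json

import numpy as np
import pandas as pd
import pytest

from biofilmnmr import quant
from biofilmnmr.errors import ConfigurationError, InputError
from biofilmnmr.synthetic import (
    GroundTruth,
    build_scenario,
    emit_dipshift,
    emit_inversion_recovery,
    emit_sugar_tables,
    ground_truth,
    render_spectrum,
    write_dataset,
)


class TestBuildScenario:
    def test_default_scenario_peaks_on_day_two(self):
        sc = build_scenario(seed=7)
        truth = ground_truth(sc)
        assert sc.days == [1, 2, 3, 4, 5]
        assert max(truth.total_biomass_by_day, key=truth.total_biomass_by_day.get) == 2
        # residual biomass on day 5 is 20% of the maximum
        ratio = truth.total_biomass_by_day[5] / truth.total_biomass_by_day[2]
        assert ratio == pytest.approx(0.20, abs=0.005)

    def test_same_config_and_seed_is_deterministic(self):
        assert build_scenario(seed=7) == build_scenario(seed=7)

    def test_out_of_range_mobile_fraction_names_key(self):
        cfg = {
            "components": {
                "x": {
                    "peaks": [(90.0, 0.5, 1.0)],
                    "biomass_by_day": {1: 1.0},
                    "mobile_fraction_by_day": {1: 1.2},
                }
            },
            "days": [1],
        }
        with pytest.raises(ConfigurationError, match="mobile_fraction_by_day"):
            build_scenario(cfg)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigurationError, match="not_a_key"):
            build_scenario({"not_a_key": 1})
        with pytest.raises(ConfigurationError, match="typo"):
            build_scenario(
                {
                    "components": {
                        "x": {
                            "peaks": [(90.0, 0.5, 1.0)],
                            "biomass_by_day": {1: 1.0},
                            "mobile_fraction_by_day": {1: 0.5},
                            "typo": 3,
                        }
                    },
                    "days": [1],
                }
            )

    def test_non_increasing_days_rejected(self):
        with pytest.raises(ConfigurationError, match="days"):
            build_scenario({"days": [1, 1, 2]})


class TestRenderSpectrum:
    def test_single_peak_qdp_matches_analytic_lorentzian(self):
        cfg = {
            "components": {
                "x": {
                    "peaks": [(90.0, 0.5, 1.0)],
                    "biomass_by_day": {1: 1.0},
                    "mobile_fraction_by_day": {1: 1.0},
                }
            },
            "days": [1],
            "sample_mass_mg_by_day": {1: 1.0},
            "scans_per_mode": {"qDP": 1, "DP2s": 1, "CP": 1},
        }
        s = render_spectrum(build_scenario(cfg), 1, "qDP")
        expected = (0.5 / np.pi) / ((s.ppm - 90.0) ** 2 + 0.25)
        assert np.allclose(s.intensity, expected, rtol=1e-12)
        # numeric area over the full axis equals the configured unit biomass
        # within Lorentzian tail truncation (< 0.5%)
        area = quant.carbon_biomass_density(s)
        assert area == pytest.approx(1.0, abs=0.005)

    @pytest.mark.parametrize(
        "t1,expected",
        [(0.3, 1.0 - np.exp(-2.0 / 0.3)), (10.0, 1.0 - np.exp(-0.2))],
    )
    def test_short_recycle_saturation_factor(self, t1, expected):
        """DP2s weights a phase by 1 - exp(-RD/T1) with RD = 2 s."""
        mf = 1.0 if t1 == 0.3 else 0.0
        cfg = {
            "components": {
                "x": {
                    "peaks": [(90.0, 0.5, 1.0)],
                    "biomass_by_day": {1: 1.0},
                    "mobile_fraction_by_day": {1: mf},
                    "t1_mobile_s": t1,
                    "t1_rigid_s": t1,
                }
            },
            "days": [1],
        }
        sc = build_scenario(cfg)
        ratio = quant.mobile_fraction(render_spectrum(sc, 1, "DP2s"), render_spectrum(sc, 1, "qDP"))
        assert ratio == pytest.approx(expected, abs=1e-6)

    def test_phase_additivity_qdp_dominates_dp2s(self, default_scenario):
        """Saturation factors <= 1: qDP area >= DP2s area >= 0, every day."""
        for day in default_scenario.days:
            q = render_spectrum(default_scenario, day, "qDP")
            m = render_spectrum(default_scenario, day, "DP2s")
            aq = quant.carbon_biomass_density(q)
            with pytest.warns(UserWarning):
                am = quant.carbon_biomass_density(m)
            assert aq >= am >= 0.0

    def test_cp_flagged_non_quantitative_and_rigid_only(self, two_phase_scenario):
        cp = render_spectrum(two_phase_scenario, 1, "CP")
        q = render_spectrum(two_phase_scenario, 1, "qDP")
        assert cp.meta["quantitative"] is False
        with pytest.warns(UserWarning):
            d_cp = quant.carbon_biomass_density(cp)
        # rigid share (0.09) x CP efficiency (0.4)
        assert d_cp / quant.carbon_biomass_density(q) == pytest.approx(0.09 * 0.4, abs=1e-3)

    def test_axis_stored_descending(self, default_scenario):
        s = render_spectrum(default_scenario, 1, "qDP")
        assert s.ppm[0] > s.ppm[-1]

    def test_unknown_mode_and_day_rejected(self, default_scenario):
        with pytest.raises(InputError):
            render_spectrum(default_scenario, 1, "INEPT")
        with pytest.raises(InputError):
            render_spectrum(default_scenario, 9, "qDP")

    def test_noise_is_seeded_and_reported_as_snr(self):
        sc1 = build_scenario({"noise_sigma": 5.0}, seed=3)
        sc2 = build_scenario({"noise_sigma": 5.0}, seed=3)
        a = render_spectrum(sc1, 1, "qDP")
        b = render_spectrum(sc2, 1, "qDP")
        assert np.array_equal(a.intensity, b.intensity)
        snr = a.intensity.max() / 5.0
        assert snr > 10


class TestEmitInversionRecovery:
    def test_model_boundaries(self, default_scenario):
        ser = emit_inversion_recovery(
            default_scenario, "MurNAc-C1", delays=np.array([0.0, 0.5, 1.0, 100.0])
        )
        assert ser.intensities[0] == pytest.approx(-1.0)   # fully inverted at t=0
        assert ser.intensities[-1] == pytest.approx(1.0)   # plateau for t >> T1
        assert np.all(np.diff(ser.intensities) > 0)

    def test_unknown_site_and_empty_grid_rejected(self, default_scenario):
        with pytest.raises(InputError):
            emit_inversion_recovery(default_scenario, "no-such-site")
        with pytest.raises(InputError):
            emit_inversion_recovery(default_scenario, "Glc-C1", delays=np.array([]))


class TestEmitDipshift:
    def test_zero_order_parameter_is_flat(self):
        sc = build_scenario({"dipshift_sites": {"iso": ("CH", 0.0)}})
        curve = emit_dipshift(sc, "iso")
        assert np.allclose(curve.intensities, 1.0, atol=1e-12)

    def test_time_zero_intensity_is_one(self, default_scenario):
        for site in default_scenario.dipshift_sites:
            curve = emit_dipshift(default_scenario, site, n_t1=8)
            assert curve.intensities[0] == pytest.approx(1.0, abs=1e-9)

    def test_invalid_multiplicity_rejected(self):
        with pytest.raises(ConfigurationError, match="multiplicity"):
            build_scenario({"dipshift_sites": {"x": ("CH3", 0.5)}})


class TestEmitSugarTables:
    def test_undetected_medium_sugar_is_missing_not_zero(self, default_scenario):
        _bio, med = emit_sugar_tables(default_scenario)
        glcn = med[med["sugar"] == "GlcN"]["integral"]
        assert len(glcn) == 5
        assert glcn.isna().all()
        # GlcA absent from the medium on day 1 only
        glca = med[med["sugar"] == "GlcA"].set_index("day")["integral"]
        assert np.isnan(glca.loc[1])
        assert glca.loc[2:].notna().all()

    def test_uniform_partition_gives_constant_features(self):
        cfg = {
            "sugars": {
                name: {
                    "family": fam,
                    "biofilm_by_day": {d: q for d, q in zip(range(1, 6), vals)},
                    "ratio_by_day": {d: 1.0 for d in range(1, 6)},
                }
                for name, fam, vals in [
                    ("A", "f1", [1, 2, 3, 2, 1]),
                    ("B", "f2", [5, 4, 3, 2, 1]),
                ]
            }
        }
        sc = build_scenario(cfg)
        bio, med = emit_sugar_tables(sc)
        from biofilmnmr.clustering import compute_ratio_features

        feats, dropped = compute_ratio_features(bio, med)
        assert not dropped
        assert np.allclose(feats.to_numpy(), 1.0)

    def test_single_family_rejected(self):
        cfg = {
            "sugars": {
                "A": {
                    "family": "f1",
                    "biofilm_by_day": {d: 1.0 for d in range(1, 6)},
                    "ratio_by_day": {d: 2.0 for d in range(1, 6)},
                }
            }
        }
        with pytest.raises(ConfigurationError, match="famil"):
            emit_sugar_tables(build_scenario(cfg))


class TestDatasetRoundTrip:
    def test_write_is_deterministic_and_ground_truth_complete(self, tmp_path):
        sc = build_scenario({"noise_sigma": 2.0, "sugar_noise_cv": 0.02}, seed=11)
        p1 = write_dataset(sc, tmp_path / "a")
        p2 = write_dataset(sc, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

        truth = GroundTruth.from_json(p1["ground_truth"].read_text())
        assert set(truth.t1_by_site) == set(sc.t1_sites)
        assert set(truth.order_parameter_by_site) == set(sc.dipshift_sites)
        assert set(truth.sugar_cluster_labels) == {s.name for s in sc.sugars}
        assert set(truth.total_biomass_by_day) == set(sc.days)

        # spectra round-trip through the text format
        from biofilmnmr.spectra import Spectrum1D

        s = Spectrum1D.read(p1["spectrum_d2_qDP"])
        assert s.mode == "qDP" and s.day == 2 and s.n_scans == sc.scans_per_mode["qDP"]

        ir = pd.read_csv(p1["inversion_recovery"])
        assert set(ir.columns) == {"site", "delay_s", "intensity", "sigma"}
        cmap = json.loads(p1["category_map"].read_text())
        assert set(cmap.values()) == set(quant.COMPONENT_CATEGORIES)
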