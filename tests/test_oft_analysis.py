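import numpy as np
import pytest

import erythrokit as ek
from erythrokit.errors import AnalysisError
from erythrokit.synth.oft import OFTRecording
from erythrokit.synth.population import GaussianSpec


def _cells(n=2000, seed=0, **overrides):
    defaults = dict(
        v300=GaussianSpec(90.0, 0.0),
        vs_fraction=GaussianSpec(0.8, 0.0),
        lysis_osm=GaussianSpec(142.0, 8.0),
        axis_ratio=GaussianSpec(0.3, 0.05, lower=0.02, upper=1.0),
    )
    defaults.update(overrides)
    return ek.sample_population(
        ek.PopulationSpec(group_label="Control", n_cells=n, seed=seed, **defaults)
    )


class TestResistanceSummary:
    def test_exact_grid_points(self):
        curve = [(160, 0), (150, 10), (140, 50), (130, 90), (120, 100)]
        s = ek.resistance_summary(curve)
        assert (s.h50, s.h10, s.h90, s.w) == (140.0, 150.0, 130.0, 20.0)

    def test_linear_interpolation_between_plateaus(self):
        curve = [(160, 0), (150, 20), (140, 60), (130, 95), (120, 100)]
        s = ek.resistance_summary(curve)
        assert s.h50 == pytest.approx(142.5)
        assert s.h10 == pytest.approx(155.0)
        assert s.h90 == pytest.approx(140 - 10 * (90 - 60) / (95 - 60))

    def test_error_names_the_unreached_threshold(self):
        with pytest.raises(AnalysisError, match="H90"):
            ek.resistance_summary([(160, 0), (150, 20), (140, 60)])

    def test_width_is_nonnegative(self):
        s = ek.resistance_summary([(160, 0), (150, 10), (140, 50), (130, 90), (120, 100)])
        assert s.w >= 0
        assert s.h90 <= s.h50 <= s.h10


class TestLysedFractionCurve:
    def test_no_lysis_gives_zero_everywhere(self):
        cells = _cells(lysis_osm=GaussianSpec(50.0, 0.0))  # below the schedule floor
        rec = ek.simulate_oft_recording(cells, seed=1)
        curve = ek.lysed_fraction_curve(rec)
        np.testing.assert_allclose(curve["lysed_pct"], 0.0, atol=1e-6)

    def test_full_lysis_at_first_hypotonic_step(self):
        cells = _cells(lysis_osm=GaussianSpec(295.0, 0.0))
        rec = ek.simulate_oft_recording(cells, seed=1)
        curve = ek.lysed_fraction_curve(rec)
        assert curve["lysed_pct"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(curve["lysed_pct"].iloc[1:], 100.0, atol=1e-6)

    def test_normal_population_crosses_half_at_its_mean(self):
        cells = _cells(n=10_000, seed=2)
        rec = ek.simulate_oft_recording(cells, seed=2)
        curve = ek.lysed_fraction_curve(rec)
        at_142 = np.interp(-142.0, -curve["osmolality_mosmol"], curve["lysed_pct"])
        assert at_142 == pytest.approx(50.0, abs=2.0)

    def test_matches_generator_truth_within_one_point(self):
        cells = _cells(n=5000, seed=3)
        rec = ek.simulate_oft_recording(cells, seed=3)
        curve = ek.lysed_fraction_curve(rec)
        for osm, lysed in zip(curve["osmolality_mosmol"], curve["lysed_pct"]):
            assert lysed == pytest.approx(100.0 * rec.lysed_truth[osm], abs=1.0)

    def test_curve_is_monotone_after_regularization(self, control_recording):
        curve = ek.lysed_fraction_curve(control_recording)
        assert np.all(np.diff(curve["lysed_pct"]) >= -1e-12)

    def test_identical_channel_sensitivities_are_rejected(self, control_recording):
        with pytest.raises(AnalysisError):
            ek.lysed_fraction_curve(control_recording, hemolysis_angle=2.5, swelling_angle=2.5)

    def test_resolution_floor_for_homogeneous_lysis(self):
        cells = _cells(lysis_osm=GaussianSpec(145.0, 0.0))
        rec = ek.simulate_oft_recording(cells, seed=4)
        s = ek.resistance_summary(ek.lysed_fraction_curve(rec))
        assert 0 < s.w <= 10.0  # bounded by the plateau spacing


class TestMcvOsmCurve:
    def test_single_isotonic_plateau_gives_the_anchor_point(self):
        rec = ek.simulate_oft_recording(_cells(), schedule=[(4.0, 300.0)], seed=1)
        curve = ek.mcv_osm_curve(rec, mcv_300=90.0)
        assert len(curve) == 1
        assert curve["osmolality_mosmol"].iloc[0] == 300.0
        assert curve["mcv_osm_fl"].iloc[0] == 90.0

    def test_recovers_vant_hoff_volume_at_200(self):
        cells = _cells(
            n=4000,
            v300=GaussianSpec(84.6, 2.9, lower=40.0),
            vs_fraction=GaussianSpec(70.6 / 84.6, 0.0),
            lysis_osm=GaussianSpec(142.0, 8.0),
        )
        rec = ek.simulate_oft_recording(cells, seed=5)
        curve = ek.mcv_osm_curve(rec, mcv_300=84.6).set_index("osmolality_mosmol")
        assert curve.loc[200.0, "mcv_osm_fl"] == pytest.approx(91.6, abs=0.5)
        assert curve.loc[300.0, "mcv_osm_fl"] == 84.6

    def test_osmotically_inactive_cells_give_a_flat_curve(self):
        cells = _cells(vs_fraction=GaussianSpec(0.999, 0.0, upper=0.999))
        rec = ek.simulate_oft_recording(cells, seed=6)
        curve = ek.mcv_osm_curve(rec, mcv_300=90.0)
        np.testing.assert_allclose(curve["mcv_osm_fl"], 90.0, atol=0.3)

    def test_nonpositive_reference_is_rejected(self, control_recording):
        with pytest.raises(AnalysisError):
            ek.mcv_osm_curve(control_recording, mcv_300=0.0)


class TestAsphericityIndex:
    def _recording(self, trace):
        n = len(trace)
        return OFTRecording(
            schedule=[(n / 100.0, 300.0)],
            angles=(2.5,),
            time_s=np.arange(n) / 100.0,
            osmolality=np.full(n, 300.0),
            sli=np.asarray(trace, dtype=float)[:, None],
            sampling_rate=100.0,
        )

    def test_constant_trace_has_zero_index(self):
        assert ek.asphericity_index(self._recording(np.full(400, 50.0))) == pytest.approx(0.0)

    def test_sinusoid_gives_peak_to_peak_over_mean(self):
        t = np.arange(1024)
        trace = 100.0 + 10.0 * np.sin(2 * np.pi * t / 64)
        # detrending over a finite window nudges the SD by ~0.1%
        assert ek.asphericity_index(self._recording(trace)) == pytest.approx(20.0, rel=5e-3)

    def test_short_plateau_is_rejected(self):
        with pytest.raises(AnalysisError):
            ek.asphericity_index(self._recording(np.full(50, 50.0)))

    def test_threefold_amplitude_reduction_gives_threefold_index_ratio(
        self, control_recording, tax_recording
    ):
        ratio = ek.asphericity_index(control_recording) / ek.asphericity_index(tax_recording)
        assert ratio == pytest.approx(3.0, rel=0.10)


def test_analyze_recording_bundles_all_statistics(control_recording):
    res = ek.analyze_recording(control_recording, mcv_300=90.0)
    assert res.h90 <= res.h50 <= res.h10
    assert res.w == pytest.approx(res.h10 - res.h90)
    assert res.asphericity_index > 0
    assert res.mcv_osm_curve["mcv_osm_fl"].iloc[0] == 90.0
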