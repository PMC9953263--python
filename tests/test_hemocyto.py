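import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import erythrokit as ek
from erythrokit.errors import AnalysisError
from erythrokit.hemocyto import GAUSSIAN_WIDTH_FACTOR
from erythrokit.synth.cyto import CytometrySpec, simulate_cytometry_events, simulate_volume_histogram


class TestHematology:
    def test_gaussian_rdw_sd_approaches_the_analytic_width(self):
        rng = np.random.default_rng(1)
        v = rng.normal(90.0, 10.0, 50_000)
        res = ek.hematology_summary(v)
        expected = GAUSSIAN_WIDTH_FACTOR * 10.0  # ~35.88 fL at 20% of peak height
        assert res.rdw_sd == pytest.approx(expected, rel=0.03)
        assert res.rdw_cv == pytest.approx(100.0 * 10.0 / 90.0, rel=0.03)
        assert res.mcv == pytest.approx(90.0, abs=0.2)

    def test_constant_volumes_have_zero_width(self):
        res = ek.hematology_summary(np.full(600, 90.0))
        assert res.rdw_sd == 0.0
        assert res.rdw_cv == 0.0
        assert res.mcv == 90.0

    def test_too_few_volumes_is_an_error(self):
        with pytest.raises(AnalysisError):
            ek.hematology_summary(np.full(100, 90.0))

    def test_multimodal_histogram_uses_widest_span_with_warning(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(70, 3, 4000), rng.normal(110, 3, 4000)])
        with pytest.warns(UserWarning, match="widest span"):
            res = ek.hematology_summary(v)
        assert res.rdw_sd > 30.0  # spans both modes


class TestMfi:
    def test_treated_equal_to_control(self, rng):
        c = rng.lognormal(5.0, 0.3, 5000)
        zero = np.zeros(1000)
        assert ek.mfi_percent(c, c, zero) == pytest.approx(100.0)

    def test_half_intensity(self):
        assert ek.mfi_percent(np.full(100, 50.0), np.full(100, 100.0), np.zeros(100)) == 50.0

    def test_negative_control_subtraction(self):
        got = ek.mfi_percent(np.full(100, 50.0), np.full(100, 100.0), np.full(100, 1.1))
        assert got == pytest.approx(100 * (50 - 1.1) / (100 - 1.1))

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(st.floats(0.1, 10.0), st.floats(0.0, 50.0))
    def test_affine_gain_invariance(self, gain, offset):
        t, c, n = np.full(50, 40.0), np.full(50, 90.0), np.full(50, 2.0)
        base = ek.mfi_percent(t, c, n)
        scaled = ek.mfi_percent(gain * t + offset, gain * c + offset, gain * n + offset)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_control_below_negative_is_an_error(self):
        with pytest.raises(AnalysisError):
            ek.mfi_percent(np.ones(10), np.ones(10), np.full(10, 2.0))


class TestGating:
    def test_unstained_against_itself_leaves_the_gate_tail(self):
        ev = simulate_cytometry_events(CytometrySpec(stained=False, seed=3))
        got = ek.positive_fraction(ev, ev, quantile=0.995)
        assert got == pytest.approx(0.5, abs=0.2)

    def test_fully_shifted_sample_is_all_positive(self):
        un = simulate_cytometry_events(CytometrySpec(stained=False, seed=4))
        st_ = un.copy()
        st_["fitc"] = un["fitc"] + un["fitc"].max()
        assert ek.positive_fraction(st_, un) == pytest.approx(100.0)

    def test_planted_positive_subpopulation_is_recovered(self):
        spec = CytometrySpec(seed=5, positive_fraction=0.10, positive_brightness=10.0,
                             fitc_median=30.0, unstained_fitc_median=30.0)
        stained = simulate_cytometry_events(spec)
        unstained = simulate_cytometry_events(
            CytometrySpec(stained=False, seed=6, unstained_fitc_median=30.0)
        )
        se = 100 * np.sqrt(0.1 * 0.9 / spec.n_events)
        got = ek.positive_fraction(stained, unstained)
        # the gate's own 0.5% tail sits on top of the planted fraction
        assert got == pytest.approx(10.0 + 0.45, abs=3 * se + 0.5)

    def test_microparticle_gate_fractions(self):
        ev = simulate_cytometry_events(CytometrySpec(seed=7, microparticle_fraction=0.05))
        assert ek.microparticle_fraction(ev, size_gate=0.0) == 0.0
        assert ek.microparticle_fraction(ev, size_gate=np.inf) == 100.0
        se = 100 * np.sqrt(0.05 * 0.95 / 20_000)
        got = ek.microparticle_fraction(ev, size_gate=3e4)  # well below the main FSC peak
        assert got == pytest.approx(5.0, abs=3 * se)


class TestCytometryGenerator:
    def test_volume_histogram_conserves_counts(self):
        cells = ek.sample_population(ek.preset_population("Control", n_cells=2000, seed=1))
        hist = simulate_volume_histogram(cells)
        assert hist.counts.sum() == 2000

    def test_constant_volumes_occupy_a_single_bin(self):
        hist = simulate_volume_histogram(np.full(500, 90.0))
        assert (hist.counts > 0).sum() == 1

    def test_lognormal_fitc_median_is_matched(self):
        ev = simulate_cytometry_events(CytometrySpec(seed=8, fitc_median=1234.0))
        assert np.median(ev["fitc"]) == pytest.approx(1234.0, rel=0.05)

    def test_event_tables_are_deterministic(self):
        a = simulate_cytometry_events(CytometrySpec(seed=9))
        b = simulate_cytometry_events(CytometrySpec(seed=9))
        assert a.equals(b)
        assert (a[["fsc", "ssc", "fitc"]] >= 0).all().all()
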