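import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import erythrokit as ek
from erythrokit.errors import AnalysisError, ConfigurationError
from erythrokit.spectro import DEFAULT_EXTINCTION
from erythrokit.synth.spectra import simulate_absorbance


class TestFreeHb:
    def test_supernatant_equal_to_lysate_is_one_hundred_percent(self):
        spec = ek.AbsorbanceSpectrum({540: 2.1, 700: 0.1}, dilution_factor=20)
        assert ek.free_hb_percent(spec, spec) == pytest.approx(100.0)

    def test_pure_turbidity_supernatant_is_zero(self):
        sup = ek.AbsorbanceSpectrum({540: 0.3, 700: 0.3})
        lys = ek.AbsorbanceSpectrum({540: 2.1, 700: 0.1})
        assert ek.free_hb_percent(sup, lys) == 0.0

    def test_worked_example(self):
        sup = ek.AbsorbanceSpectrum({540: 0.5, 700: 0.1})
        lys = ek.AbsorbanceSpectrum({540: 2.1, 700: 0.1})
        assert ek.free_hb_percent(sup, lys) == pytest.approx(20.0)

    def test_dilution_factors_scale_the_ratio(self):
        sup = ek.AbsorbanceSpectrum({540: 0.5, 700: 0.1}, dilution_factor=20)
        lys = ek.AbsorbanceSpectrum({540: 2.1, 700: 0.1}, dilution_factor=200)
        assert ek.free_hb_percent(sup, lys) == pytest.approx(2.0)

    def test_signal_free_lysate_is_rejected(self):
        sup = ek.AbsorbanceSpectrum({540: 0.5, 700: 0.1})
        lys = ek.AbsorbanceSpectrum({540: 0.1, 700: 0.1})
        with pytest.raises(AnalysisError):
            ek.free_hb_percent(sup, lys)


class TestSpeciesUnmixing:
    def test_pure_species_is_identified_exactly(self):
        spec = simulate_absorbance((0.0, 1.0, 0.0), total_hb=0.2)
        fr = ek.hb_species_fractions(spec)
        assert fr.fractions["methb"] == pytest.approx(1.0, abs=1e-10)
        assert fr.residual == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_mixture_is_recovered_to_machine_precision(self):
        spec = simulate_absorbance((0.7, 0.2, 0.1), total_hb=0.15)
        fr = ek.hb_species_fractions(spec)
        assert fr.fractions["oxyhb"] == pytest.approx(0.7, abs=1e-8)
        assert fr.fractions["methb"] == pytest.approx(0.2, abs=1e-8)
        assert fr.fractions["hemichrome"] == pytest.approx(0.1, abs=1e-8)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(st.floats(0.1, 50.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_fractions_are_scale_invariant(self, scale, a, b):
        f = np.array([a, b, 1.0])
        f /= f.sum()
        base = simulate_absorbance(f, total_hb=0.2, turbidity_offset=0.0)
        scaled = ek.AbsorbanceSpectrum({w: v * scale for w, v in base.od.items()})
        fr0 = ek.hb_species_fractions(base)
        fr1 = ek.hb_species_fractions(scaled)
        for s in fr0.fractions:
            assert fr1.fractions[s] == pytest.approx(fr0.fractions[s], abs=1e-9)

    def test_nnls_agrees_with_unconstrained_solve_when_nonnegative(self):
        rng = np.random.default_rng(3)
        a = DEFAULT_EXTINCTION.loc[[560.0, 577.0, 630.0]].to_numpy()
        for _ in range(50):
            f = rng.dirichlet((2, 2, 2))
            spec = simulate_absorbance(f, total_hb=0.2, noise_sd=0.003, seed=rng.integers(2**31))
            b = np.array([spec.od[w] - spec.od[700.0] for w in (560.0, 577.0, 630.0)])
            direct = np.linalg.solve(a, b)
            if np.all(direct >= 0):
                got = ek.hb_species_fractions(spec)
                np.testing.assert_allclose(
                    list(got.fractions.values()), direct / direct.sum(), atol=1e-8
                )

    def test_noise_robustness_rmse(self):
        rng = np.random.default_rng(5)
        errs = []
        for s in range(100):
            f = rng.dirichlet((5, 2, 1))
            spec = simulate_absorbance(f, total_hb=0.2, noise_sd=0.005, seed=s)
            got = ek.hb_species_fractions(spec)
            errs.append(np.array(list(got.fractions.values())) - f)
        assert np.sqrt(np.mean(np.square(errs))) < 0.02

    def test_ill_conditioned_matrix_is_rejected(self):
        bad = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0], "c": [0.5, 1.0, 1.5]},
            index=pd.Index([560.0, 577.0, 630.0], name="wavelength_nm"),
        )
        spec = simulate_absorbance((0.5, 0.3, 0.2), total_hb=0.2)
        with pytest.raises(ConfigurationError):
            ek.hb_species_fractions(spec, extinction=bad)

    def test_zero_corrected_spectrum_is_rejected(self):
        spec = ek.AbsorbanceSpectrum({560: 0.1, 577: 0.1, 630: 0.1, 700: 0.1})
        with pytest.raises(AnalysisError):
            ek.hb_species_fractions(spec)


class TestAbsorbanceGenerator:
    def test_zero_hemoglobin_gives_pure_turbidity(self):
        spec = simulate_absorbance((1.0, 0.0, 0.0), total_hb=0.0, turbidity_offset=0.1)
        assert all(v == pytest.approx(0.1) for v in spec.od.values())

    def test_pure_species_spectrum_is_the_scaled_extinction_column(self):
        spec = simulate_absorbance((1.0, 0.0, 0.0), total_hb=0.2, turbidity_offset=0.0,
                                   pathlength_cm=1.0)
        for w in DEFAULT_EXTINCTION.index:
            assert spec.od[w] == pytest.approx(0.2 * DEFAULT_EXTINCTION.loc[w, "oxyhb"])

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            simulate_absorbance((0.5, 0.2, 0.1))

    def test_negative_od_is_rejected(self):
        with pytest.raises(ConfigurationError):
            ek.AbsorbanceSpectrum({540: -0.1, 700: 0.0})
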