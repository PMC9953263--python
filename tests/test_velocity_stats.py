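import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps

import erythrokit as ek
from erythrokit.errors import AnalysisError
from erythrokit.synth.micro import VelocityDataset
from erythrokit.synth.population import GaussianSpec, velocity_mixture


class TestVelocityPdf:
    def test_single_bin_density_is_inverse_bin_width(self):
        pdf = ek.velocity_pdf([np.full(100, 1.01)], bin_width=0.025)
        occupied = pdf[pdf["density_mean"] > 0]
        assert len(occupied) == 1
        assert occupied["density_mean"].iloc[0] == pytest.approx(1 / 0.025)

    def test_identical_experiments_have_zero_standard_error(self):
        v = np.random.default_rng(0).normal(1.0, 0.2, 2000).clip(0)
        pdf = ek.velocity_pdf([v, v.copy()])
        np.testing.assert_allclose(pdf["density_se"], 0.0)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(
        hnp.arrays(
            float,
            st.integers(10, 400),
            elements=st.floats(0.0, 3.5, allow_nan=False),
        )
    )
    def test_each_experiment_density_integrates_to_one(self, velocities):
        pdf = ek.velocity_pdf([velocities], bin_width=0.025)
        assert (pdf["density_mean"] * 0.025).sum() == pytest.approx(1.0, abs=1e-6)

    def test_averaged_pdf_matches_the_generating_density(self):
        rng = np.random.default_rng(7)
        draws = [rng.normal(1.0, 0.15, 5000).clip(0) for _ in range(10)]
        pdf = ek.velocity_pdf(draws)
        expected = sps.norm.pdf(pdf["bin_center"], 1.0, 0.15)
        mask = expected > 1e-4
        err = np.abs(pdf["density_mean"] - expected)[mask]
        tol = 3 * pdf["density_se"][mask] + 3 * expected[mask] * 0.02 + 0.02
        assert np.all(err <= tol)

    def test_empty_input_is_rejected(self):
        with pytest.raises(AnalysisError):
            ek.velocity_pdf([])


class TestSlowFastFractions:
    def test_direct_count(self):
        fr = ek.slow_fast_fractions([0.1, 0.5, 1.0, 1.2], cutoff_slow=0.175)
        assert fr.slow_pct == pytest.approx(25.0)

    def test_fast_fraction_counts_above_cutoff(self):
        fr = ek.slow_fast_fractions([0.1, 0.5, 1.0, 1.6], cutoff_slow=0.175, cutoff_fast=1.4)
        assert fr.fast_pct == pytest.approx(25.0)

    def test_control_normal_sits_below_the_paper_bound(self):
        spec = ek.PopulationSpec(
            group_label="Control", n_cells=20_000, seed=5,
            velocity=velocity_mixture(main=GaussianSpec(1.0, 0.30, lower=0.0)),
        )
        ds = ek.simulate_velocity_dataset(spec)
        assert ek.slow_fast_fractions(ds).slow_pct < 0.45

    @pytest.mark.parametrize("weight", [0.089, 0.047, 0.098])
    def test_mixture_weight_recovery(self, weight):
        spec = ek.PopulationSpec(
            group_label="mix", n_cells=20_000, seed=int(weight * 1e4),
            velocity=velocity_mixture(
                slow_weight=weight, main=GaussianSpec(1.0, 0.15, lower=0.0)
            ),
        )
        ds = ek.simulate_velocity_dataset(spec)
        se = 100 * np.sqrt(weight * (1 - weight) / 20_000)
        assert ek.slow_fast_fractions(ds).slow_pct == pytest.approx(100 * weight, abs=3 * se)


class TestCalibrateCutoff:
    def test_half_tail_mass_returns_the_median(self, rng):
        v = rng.normal(1.0, 0.3, 5000)
        assert ek.calibrate_cutoff(v, 0.5) == pytest.approx(np.median(v))

    def test_zero_tail_mass_returns_the_minimum(self, rng):
        v = rng.normal(1.0, 0.3, 5000)
        assert ek.calibrate_cutoff(v, 0.0) == v.min()

    def test_control_construction_reproduces_the_field_cutoff(self, rng):
        v = rng.normal(1.0, 0.316, 200_000)
        assert ek.calibrate_cutoff(v, 0.0045) == pytest.approx(0.175, abs=0.01)

    def test_small_samples_are_rejected(self, rng):
        with pytest.raises(AnalysisError):
            ek.calibrate_cutoff(rng.normal(1.0, 0.3, 500))

    def test_fast_cutoff_mirrors_the_slow_construction(self, rng):
        v = rng.normal(1.0, 0.3, 50_000)
        fast = ek.calibrate_fast_cutoff(v, tail_mass=0.0025)
        assert fast == pytest.approx(np.quantile(v, 0.9975))
        assert ek.slow_fast_fractions(v, cutoff_fast=fast).fast_pct == pytest.approx(
            0.25, abs=100.0 / 50_000
        )

    def test_roundtrip_with_slow_fraction_is_consistent(self, rng):
        v = rng.normal(1.0, 0.3, 20_000).clip(0.001)
        cutoff = ek.calibrate_cutoff(v, 0.0045)
        got = ek.slow_fast_fractions(v, cutoff_slow=cutoff).slow_pct
        assert got == pytest.approx(0.45, abs=100.0 / 20_000)


class TestOcclusions:
    def test_direct_fraction(self):
        ds = VelocityDataset(np.ones(8), channel_occluded=[1, 1, 0, 0, 0, 0, 0, 0])
        res = ek.occlusion_rate([ds])
        assert res.rate_pct == pytest.approx(25.0)
        assert res.n_channels == 8

    def test_no_flags_means_zero_rate(self):
        ds = VelocityDataset(np.ones(4), channel_occluded=np.zeros(4, bool))
        assert ek.occlusion_rate([ds]).rate_pct == 0.0

    def test_zero_channels_is_an_error(self):
        ds = VelocityDataset(np.ones(4), channel_occluded=np.zeros(0, bool))
        with pytest.raises(AnalysisError):
            ek.occlusion_rate([ds])

    def test_bernoulli_arrest_rate_is_recovered(self):
        spec = ek.PopulationSpec(
            group_label="adh", n_cells=200, seed=1, adhesion_propensity=0.1,
            velocity=velocity_mixture(main=GaussianSpec(1.0, 0.15, lower=0.0)),
        )
        rates = [
            ek.occlusion_rate([ek.simulate_velocity_dataset(spec, n_channels=200, seed=s)]).rate_pct
            for s in range(5)
        ]
        # ~1 cell per channel: occlusion probability 1 - (1 - p/200)^200 ~ 9.5%
        assert np.mean(rates) == pytest.approx(9.5, abs=3 * 100 * np.sqrt(0.1 * 0.9 / 1000))


def test_analyze_velocity_datasets_bundles_pdf_fractions_and_occlusions():
    spec = ek.PopulationSpec(
        group_label="mix", n_cells=5000, seed=2, adhesion_propensity=0.001,
        velocity=velocity_mixture(slow_weight=0.08, main=GaussianSpec(1.0, 0.15, lower=0.0)),
    )
    datasets = [ek.simulate_velocity_dataset(spec, seed=s) for s in range(3)]
    res = ek.analyze_velocity_datasets(datasets)
    assert res.slow_fraction_pct == pytest.approx(8.0, abs=1.5)
    assert (res.pdf["density_mean"] * 0.025).sum() == pytest.approx(1.0, abs=1e-6)
    assert res.occlusion_rate_pct is not None
    assert len(res.per_experiment_slow_pct) == 3
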