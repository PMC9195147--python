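import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xasmelt import synth, xanes
from xasmelt.synth import GaussianFeature, ReferenceProfile, make_mixture, make_reference_xanes
from xasmelt.types import Spectrum


def _as_normalized(spec, e0):
    """Wrap an already-normalized spectrum without re-fitting baselines."""
    return xanes.NormalizedXanes(spec.energies, spec.mu, e0=e0, edge_step=1.0,
                                 label=spec.label)


class TestEdgeEnergy:
    def test_arctan_step_center(self, energy_grid):
        s = make_reference_xanes(ReferenceProfile(e0=7725.0), energy_grid)
        assert xanes.edge_energy(s) == pytest.approx(7725.0, abs=0.5)

    def test_linear_slope_does_not_move_edge(self, energy_grid):
        s = make_reference_xanes(ReferenceProfile(e0=7725.0), energy_grid)
        tilted = s.with_mu(s.mu + 0.0003 * (energy_grid - energy_grid[0]))
        assert xanes.edge_energy(tilted) == pytest.approx(xanes.edge_energy(s), abs=0.1)

    def test_matches_dense_finite_difference_oracle(self):
        grid = np.arange(7500.0, 8000.0, 0.5)
        s = make_reference_xanes(synth.BOUND_PROFILE, grid)
        # oracle: argmax of finite differences on a 100x denser resampling
        dense = np.arange(7500.0, 7999.5, 0.005)
        mu_d = np.interp(dense, grid, s.mu)
        d = np.diff(mu_d) / np.diff(dense)
        oracle = 0.5 * (dense[np.argmax(d)] + dense[np.argmax(d) + 1])
        assert xanes.edge_energy(s) == pytest.approx(oracle, abs=0.5)

    def test_flat_spectrum_rejected(self):
        e = np.arange(7500.0, 7600.0, 1.0)
        with pytest.raises(ValueError, match="flat"):
            xanes.edge_energy(Spectrum(e, np.full_like(e, 0.3)))


class TestNormalize:
    def test_scale_invariance(self, energy_grid):
        s = make_reference_xanes(synth.BOUND_PROFILE, energy_grid)
        n1 = xanes.normalize(s)
        n2 = xanes.normalize(s.with_mu(7.3 * s.mu))
        np.testing.assert_allclose(n1.norm_mu, n2.norm_mu, atol=1e-9)
        assert n2.edge_step == pytest.approx(7.3 * n1.edge_step)

    def test_step_on_sloped_preedge_recovers_unit_postedge(self):
        grid = np.arange(7450.0, 8050.0, 0.5)
        line = 0.1 + 0.0002 * (grid - 7600.0)
        step = 0.5 + np.arctan((grid - 7720.0) / 2.0) / np.pi
        s = Spectrum(grid, line + 0.4 * step, label="constructed")
        n = xanes.normalize(s, e0=7720.0)
        post = (grid >= 7720.0 + 50.0) & (grid <= 7720.0 + 300.0)
        assert np.mean(n.norm_mu[post]) == pytest.approx(1.0, abs=0.01)
        assert n.edge_step == pytest.approx(0.4, abs=0.02)

    def test_idempotent_on_own_output(self, energy_grid):
        s = make_reference_xanes(synth.BOUND_PROFILE, energy_grid)
        n1 = xanes.normalize(s)
        n2 = xanes.normalize(Spectrum(n1.energies, n1.norm_mu), e0=n1.e0)
        np.testing.assert_allclose(n2.norm_mu, n1.norm_mu, atol=1e-6)

    def test_inverted_spectrum_rejected(self, energy_grid):
        s = make_reference_xanes(ReferenceProfile(e0=7720.0), energy_grid)
        with pytest.raises(ValueError, match="edge step"):
            xanes.normalize(s.with_mu(1.0 - s.mu), e0=7720.0)


class TestPreEdgePeak:
    def test_pre_edge_center_recovered(self, bound_norm):
        peak = xanes.pre_edge_peak(bound_norm)
        assert peak.present
        assert peak.center == pytest.approx(7710.0, abs=0.5)

    def test_absence_flag_without_feature(self, energy_grid):
        s = make_reference_xanes(ReferenceProfile(e0=7720.0), energy_grid)
        peak = xanes.pre_edge_peak(xanes.normalize(s))
        assert not peak.present

    def test_height_scales_linearly(self, energy_grid):
        def fit(height):
            prof = ReferenceProfile(e0=7720.0,
                                    pre_edge=GaussianFeature(7710.0, height, 1.5),
                                    features=(GaussianFeature(7727.0, 0.45, 4.0),))
            n = xanes.normalize(make_reference_xanes(prof, energy_grid))
            return xanes.pre_edge_peak(n).height

        assert fit(0.10) == pytest.approx(2.0 * fit(0.05), rel=0.05)


class TestLcf:
    def test_target_equals_component(self, bound_norm, buffer_norm):
        res = xanes.lcf(bound_norm, bound_norm, buffer_norm)
        assert res.fractions[0] == pytest.approx(1.0, abs=1e-12)
        assert res.residual == pytest.approx(0.0, abs=1e-12)

    def test_43_57_mixture_recovered(self, bound_norm, buffer_norm):
        mix = make_mixture([bound_norm.as_spectrum(), buffer_norm.as_spectrum()],
                           [0.43, 0.57])
        res = xanes.lcf(_as_normalized(mix, bound_norm.e0), bound_norm, buffer_norm)
        assert res.fractions[0] == pytest.approx(0.43, abs=0.005)

    def test_matches_grid_search_oracle_on_random_instances(self, bound_norm, buffer_norm):
        rng = np.random.default_rng(11)
        e0 = bound_norm.e0
        grid_f = np.arange(0.0, 1.0 + 1e-12, 1e-4)
        e = bound_norm.energies
        window = (e >= e0 - 20.0) & (e <= e0 + 80.0)
        a = bound_norm.norm_mu[window]
        b = buffer_norm.norm_mu[window]
        for _ in range(100):
            f_true = rng.uniform()
            noise = rng.normal(0.0, 0.002, size=len(bound_norm.energies))
            target = f_true * bound_norm.norm_mu + (1 - f_true) * buffer_norm.norm_mu + noise
            res = xanes.lcf(xanes.NormalizedXanes(e, target, e0=e0, edge_step=1.0),
                            bound_norm, buffer_norm)
            t = target[window]
            sse = np.sum((t[None, :] - np.outer(grid_f, a)
                          - np.outer(1 - grid_f, b)) ** 2, axis=1)
            f_oracle = grid_f[np.argmin(sse)]
            assert abs(res.fractions[0] - f_oracle) <= 1e-4

    def test_noisy_fit_close_to_truth(self, bound_norm, buffer_norm):
        rng = np.random.default_rng(3)
        f_true = 0.25
        target = (f_true * bound_norm.norm_mu + (1 - f_true) * buffer_norm.norm_mu
                  + rng.normal(0.0, 0.005, size=len(bound_norm.energies)))
        res = xanes.lcf(xanes.NormalizedXanes(bound_norm.energies, target,
                                              e0=bound_norm.e0, edge_step=1.0),
                        bound_norm, buffer_norm)
        assert res.fractions[0] == pytest.approx(f_true, abs=0.02)

    @settings(max_examples=40, deadline=None)
    @given(f_true=st.floats(0.0, 1.0))
    def test_noiseless_recovery_exact_over_unit_interval(self, f_true):
        grid = synth.default_energy_grid()
        a = xanes.normalize(make_reference_xanes(synth.BOUND_PROFILE, grid))
        b = xanes.normalize(make_reference_xanes(synth.BUFFER_PROFILE, grid))
        target = f_true * a.norm_mu + (1 - f_true) * b.norm_mu
        res = xanes.lcf(xanes.NormalizedXanes(grid, target, e0=a.e0, edge_step=1.0), a, b)
        assert res.fractions[0] == pytest.approx(f_true, abs=1e-9)
        assert 0.0 <= res.fractions[0] <= 1.0
        assert res.fractions[0] + res.fractions[1] == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_components_rejected(self, bound_norm):
        with pytest.raises(ValueError, match="degenerate"):
            xanes.lcf(bound_norm, bound_norm, bound_norm)


class TestDifferenceSpectrum:
    def test_perfect_fit_gives_zeros(self, bound_norm, buffer_norm):
        res = xanes.lcf(bound_norm, bound_norm, buffer_norm)
        diff = xanes.difference_spectrum(bound_norm, res, bound_norm, buffer_norm)
        np.testing.assert_allclose(diff.mu, 0.0, atol=1e-12)

    def test_noise_level_reflected_in_rms(self, bound_norm, buffer_norm):
        rng = np.random.default_rng(5)
        sd = 0.005
        target = (0.5 * bound_norm.norm_mu + 0.5 * buffer_norm.norm_mu
                  + rng.normal(0.0, sd, size=len(bound_norm.energies)))
        nt = xanes.NormalizedXanes(bound_norm.energies, target,
                                   e0=bound_norm.e0, edge_step=1.0)
        res = xanes.lcf(nt, bound_norm, buffer_norm)
        diff = xanes.difference_spectrum(nt, res, bound_norm, buffer_norm)
        rms = float(np.sqrt(np.mean(diff.mu**2)))
        assert 0.5 * sd < rms < 1.5 * sd
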