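from dataclasses import replace

import numpy as np
import pytest

from xasmelt import exafs, synth, xanes
from xasmelt.exafs import (
    ExafsSignal,
    MetalSiteModel,
    ScatteringShell,
    excise_sphere,
    extract_chi,
    forward_chi,
    group_shells,
    r_factor,
    refine,
)
from xasmelt.synth import make_exafs_spectrum, make_site_geometry


KGRID = np.arange(2.0, 14.0, 0.05)


class TestForwardChi:
    def test_zero_shells_zero_signal(self, oxygen_table):
        m = MetalSiteModel(shells=())
        np.testing.assert_array_equal(forward_chi(m, oxygen_table, KGRID).chi, 0.0)

    def test_linear_in_coordination_number(self, oxygen_table):
        one = MetalSiteModel(shells=(ScatteringShell(1, 2.02),))
        two = MetalSiteModel(shells=(ScatteringShell(2, 2.02),))
        np.testing.assert_allclose(forward_chi(two, oxygen_table, KGRID).chi,
                                   2.0 * forward_chi(one, oxygen_table, KGRID).chi,
                                   rtol=1e-12)

    def test_linear_in_s02(self, octahedral_site_model, oxygen_table):
        base = forward_chi(replace(octahedral_site_model, s02=0.55), oxygen_table, KGRID)
        doubled = forward_chi(replace(octahedral_site_model, s02=1.1), oxygen_table, KGRID)
        np.testing.assert_allclose(doubled.chi, 2.0 * base.chi, rtol=1e-12)

    def test_zero_crossings_match_phase_closed_form(self, oxygen_table):
        # with the linear phase pi - 0.9k the sine argument is 2kR + pi - 0.9k,
        # so chi vanishes exactly at k = (m - 1)*pi / (2R - 0.9)
        r = 2.02
        m = MetalSiteModel(delta_ef=0.0, shells=(ScatteringShell(1, r),))
        sig = forward_chi(m, oxygen_table, KGRID)
        from scipy.interpolate import InterpolatedUnivariateSpline

        spline = InterpolatedUnivariateSpline(sig.k, sig.chi, k=3)
        roots = spline.roots()
        for mm in range(3, 13):
            k_expected = (mm - 1) * np.pi / (2 * r - 0.9)
            if KGRID[0] + 0.2 < k_expected < KGRID[-1] - 0.2:
                assert np.min(np.abs(roots - k_expected)) < 1e-6

    def test_sigma2_damping_is_monotone(self, oxygen_table):
        lo = MetalSiteModel(shells=(ScatteringShell(1, 2.02, sigma2=0.002),))
        hi = MetalSiteModel(shells=(ScatteringShell(1, 2.02, sigma2=0.004),))
        chi_lo = np.abs(forward_chi(lo, oxygen_table, KGRID).chi)
        chi_hi = np.abs(forward_chi(hi, oxygen_table, KGRID).chi)
        assert np.all(chi_hi <= chi_lo + 1e-15)

    def test_imaginary_wavenumber_rejected(self, oxygen_table):
        m = MetalSiteModel(delta_ef=-10.0, shells=(ScatteringShell(1, 2.0),))
        with pytest.raises(ValueError, match="imaginary"):
            forward_chi(m, oxygen_table, np.arange(0.1, 5.0, 0.05))


class TestExciseSphere:
    def test_closed_boundary_excludes_beyond_radius(self):
        atoms = make_site_geometry([(1, 5.1)])
        kept = excise_sphere(atoms, "Co", 5.0)
        assert len(kept) == 1  # absorber only

    def test_first_shell_keeps_six_oxygens(self):
        atoms = make_site_geometry([(4, 2.02), (1, 2.21), (1, 1.85)])
        kept = excise_sphere(atoms, "Co", 2.5)
        assert sum(a.element == "O" for a in kept) == 6

    def test_zero_radius_keeps_center_only(self):
        atoms = make_site_geometry([(4, 2.02), (1, 2.21), (1, 1.85)])
        kept = excise_sphere(atoms, "Co", 0.0)
        assert len(kept) == 1 and kept[0].element == "Co"

    def test_ambiguous_center_rejected(self):
        atoms = make_site_geometry([(1, 2.0)]) + make_site_geometry([(1, 2.0)])
        with pytest.raises(ValueError, match="exactly one"):
            excise_sphere(atoms, "Co", 5.0)


class TestGroupShells:
    def test_octahedral_distances_group_4_1_1(self):
        atoms = make_site_geometry([(4, 2.02), (1, 2.21), (1, 1.85)])
        model = group_shells(atoms, tol=0.1)
        counts = sorted(s.n for s in model.shells)
        assert counts == [1, 1, 4]
        four = next(s.r for s in model.shells if s.n == 4)
        singles = sorted(s.r for s in model.shells if s.n == 1)
        assert four == pytest.approx(2.02, abs=1e-6)
        assert singles == pytest.approx([1.85, 2.21], abs=1e-6)

    def test_tolerance_controls_merging(self):
        close = make_site_geometry([(1, 2.00), (1, 2.09)])
        merged = group_shells(close, tol=0.1)
        assert len(merged.shells) == 1
        assert merged.shells[0].n == 2
        assert merged.shells[0].r == pytest.approx(2.045)
        split = group_shells(close, tol=0.05)
        assert len(split.shells) == 2

    def test_single_ligand(self):
        model = group_shells(make_site_geometry([(1, 2.0)]))
        assert len(model.shells) == 1 and model.shells[0].n == 1

    def test_no_ligands_rejected(self):
        with pytest.raises(ValueError, match="no ligand"):
            group_shells(make_site_geometry([]))


class TestRFactor:
    def test_identical_signals_zero(self, octahedral_site_model, oxygen_table):
        sig = forward_chi(octahedral_site_model, oxygen_table, KGRID)
        assert r_factor(sig, sig) == pytest.approx(0.0, abs=1e-12)

    def test_zero_model_is_100_percent(self, octahedral_site_model, oxygen_table):
        sig = forward_chi(octahedral_site_model, oxygen_table, KGRID)
        zero = ExafsSignal(sig.k, np.zeros_like(sig.chi))
        assert r_factor(sig, zero) == pytest.approx(100.0)

    def test_half_model_is_50_percent(self, octahedral_site_model, oxygen_table):
        sig = forward_chi(octahedral_site_model, oxygen_table, KGRID)
        half = ExafsSignal(sig.k, 0.5 * sig.chi)
        assert r_factor(sig, half) == pytest.approx(50.0)

    def test_invariant_under_joint_rescaling(self, octahedral_site_model, oxygen_table):
        sig = forward_chi(octahedral_site_model, oxygen_table, KGRID)
        model = ExafsSignal(sig.k, 0.7 * sig.chi)
        scaled_obs = ExafsSignal(sig.k, 3.0 * sig.chi)
        scaled_model = ExafsSignal(sig.k, 3.0 * 0.7 * sig.chi)
        assert r_factor(sig, model) == pytest.approx(r_factor(scaled_obs, scaled_model))

    def test_zero_observation_rejected(self):
        z = ExafsSignal(KGRID, np.zeros_like(KGRID))
        with pytest.raises(ValueError, match="zero"):
            r_factor(z, z)


class TestExtractChi:
    def test_smooth_spectrum_gives_negligible_chi(self, oxygen_table):
        m = MetalSiteModel(e0=7720.0, shells=())
        grid = np.arange(7520.0, 8380.0, 0.5)
        norm = xanes.normalize(make_exafs_spectrum(m, oxygen_table, grid), e0=7720.0)
        sig = extract_chi(norm, rbkg=1.0)
        window = (sig.k >= 2.0) & (sig.k <= 10.0)
        assert np.max(np.abs(sig.chi[window])) < 1e-3

    def test_roundtrip_correlation(self, octahedral_site_model, oxygen_table):
        grid = np.arange(7520.0, 8380.0, 0.5)
        spec = make_exafs_spectrum(octahedral_site_model, oxygen_table, grid)
        norm = xanes.normalize(spec, e0=octahedral_site_model.e0)
        sig = extract_chi(norm, rbkg=1.0)
        window = (sig.k >= 3.0) & (sig.k <= 10.0)
        truth = forward_chi(octahedral_site_model, oxygen_table, sig.k[window]).chi
        corr = np.corrcoef(sig.chi[window], truth)[0, 1]
        assert corr > 0.99

    def test_degenerate_rbkg_rejected(self, bound_norm):
        with pytest.raises(ValueError, match="rbkg"):
            extract_chi(bound_norm, rbkg=0.0)

    def test_short_range_rejected(self, bound_norm):
        # reference XANES grid extends only 300 eV above the edge
        with pytest.raises(ValueError, match="400 eV"):
            extract_chi(bound_norm, rbkg=1.0)


class TestRefine:
    def test_truth_start_is_fixed_point(self, octahedral_site_model, oxygen_table):
        obs = forward_chi(octahedral_site_model, oxygen_table, KGRID)
        fit = refine(obs, octahedral_site_model, oxygen_table)
        assert fit.r_factor < 0.1
        for s_fit, s_true in zip(fit.model.shells, octahedral_site_model.shells):
            assert s_fit.r == pytest.approx(s_true.r, abs=1e-4)

    def test_perturbed_start_recovers_truth(self, octahedral_site_model, oxygen_table):
        obs = forward_chi(octahedral_site_model, oxygen_table, KGRID)
        start = replace(octahedral_site_model, delta_ef=0.0,
                        shells=tuple(replace(s, r=s.r + 0.10)
                                     for s in octahedral_site_model.shells))
        fit = refine(obs, start, oxygen_table, free=("radii", "ef"),
                     k_range=(3.0, 12.0), k_weight=2)
        assert fit.converged
        for s_fit, s_true in zip(fit.model.shells, octahedral_site_model.shells):
            assert s_fit.r == pytest.approx(s_true.r, abs=0.01)
        assert fit.model.delta_ef == pytest.approx(3.0, abs=0.3)

    def test_rigid_group_shares_one_offset(self, oxygen_table):
        truth = MetalSiteModel(
            delta_ef=0.0,
            shells=(ScatteringShell(2, 2.00), ScatteringShell(1, 2.30)),
            rigid_groups={0: "glu", 1: "glu"},
        )
        obs = forward_chi(truth, oxygen_table, KGRID)
        start = replace(truth, shells=tuple(replace(s, r=s.r + 0.07)
                                            for s in truth.shells))
        fit = refine(obs, start, oxygen_table, free=("radii",))
        offsets = [s_fit.r - s_start.r
                   for s_fit, s_start in zip(fit.model.shells, start.shells)]
        assert offsets[0] == pytest.approx(offsets[1], abs=1e-10)

    def test_refined_model_respects_bounds(self, oxygen_table):
        truth = MetalSiteModel(shells=(ScatteringShell(1, 1.10),))
        obs = forward_chi(truth, oxygen_table, KGRID)
        start = MetalSiteModel(shells=(ScatteringShell(1, 1.05),))
        fit = refine(obs, start, oxygen_table, free=("radii",))
        assert 1.0 < fit.model.shells[0].r < 6.0

    def test_empty_mask_rejected(self, octahedral_site_model, oxygen_table):
        obs = forward_chi(octahedral_site_model, oxygen_table, KGRID)
        with pytest.raises(ValueError, match="mask"):
            refine(obs, octahedral_site_model, oxygen_table, free=())


class TestExtractionRefinementRoundTrip:
    def test_random_models_recover_radii(self, oxygen_table):
        """Forward -> embed in background -> extract -> refine recovers radii."""
        rng = np.random.default_rng(7)
        grid = np.arange(7520.0, 8380.0, 0.5)
        for _ in range(20):
            n_shells = int(rng.integers(1, 4))
            radii = np.sort(rng.uniform(1.8, 2.5, n_shells))
            if n_shells > 1 and np.any(np.diff(radii) <= 0.15):
                radii = np.linspace(1.8, 2.5, n_shells)
            shells = tuple(ScatteringShell(int(rng.integers(1, 5)), float(r))
                           for r in radii)
            truth = MetalSiteModel(e0=7720.0, delta_ef=float(rng.uniform(-5, 5)),
                                   s02=0.9, shells=shells)
            spec = make_exafs_spectrum(truth, oxygen_table, grid)
            norm = xanes.normalize(spec, e0=truth.e0)
            sig = extract_chi(norm)
            start = replace(truth, shells=tuple(replace(s, r=s.r + 0.05)
                                                for s in truth.shells))
            fit = refine(sig, start, oxygen_table, free=("radii",))
            for s_fit, s_true in zip(fit.model.shells, truth.shells):
                assert s_fit.r == pytest.approx(s_true.r, abs=0.01)
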