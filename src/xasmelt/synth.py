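"""Synthetic-data generators with known ground truth.

Every input the analysis needs — Co K-edge XANES reference profiles, their
mixtures, raw μ(E) carrying EXAFS oscillations from a specified coordination
site on a smooth spline background, CD melting curves, and the octahedral
Co–O site geometry — is generated here as a pure function of its parameters
and a seed.  Defaults emulate the study conditions: a cobalt K edge near
7720 eV with the 1s→3d pre-edge feature near 7710 eV typical of an
octahedral site, and thermal scans on a 0.5 °C grid from 20 to 95 °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .types import AtomRecord, MeltingCurve, Spectrum

__all__ = [
    "ReferenceProfile",
    "GaussianFeature",
    "TransitionModel",
    "make_reference_xanes",
    "make_mixture",
    "make_site_geometry",
    "make_exafs_spectrum",
    "make_melting_curve",
    "default_background_points",
    "BOUND_PROFILE",
    "BUFFER_PROFILE",
    "DEFAULT_NOISE_SD_MU",
    "DEFAULT_NOISE_SD_THETA",
]

R_GAS = 8.31446261815324e-3  # kJ mol⁻¹ K⁻¹

#: Default Gaussian noise, sd in normalized μ units (spectra) — study noise
#: levels are not stated by the source data, so a realistic dilute-fluorescence
#: value is fixed here once; acceptance runs use 0.
DEFAULT_NOISE_SD_MU = 0.002
#: Default Gaussian noise on Θ₂₂₂, deg·cm²·dmol⁻¹ (~1% of a typical range).
DEFAULT_NOISE_SD_THETA = 150.0


@dataclass(frozen=True)
class GaussianFeature:
    """A Gaussian spectral feature: center (eV), height, width sigma (eV)."""

    center: float
    height: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("feature width must be positive")

    def __call__(self, e: np.ndarray) -> np.ndarray:
        return self.height * np.exp(-0.5 * ((e - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class ReferenceProfile:
    """Phenomenological XANES reference shape.

    The edge is an arctan step of unit height centered at ``e0`` with
    half-width ``edge_width``; an optional pre-edge Gaussian (the 1s→3d
    transition of a Co²⁺ site) sits below the edge, post-edge Gaussians model
    white-line and shape resonances, and ``post_slope`` tilts the post-edge
    region while the pre-edge stays flat at zero.
    """

    e0: float = 7720.0
    edge_width: float = 2.0
    pre_edge: GaussianFeature | None = None
    features: tuple = ()
    post_slope: float = 0.0

    def __post_init__(self):
        if self.edge_width <= 0:
            raise ValueError("edge width must be positive")
        if self.pre_edge is not None and self.pre_edge.center >= self.e0:
            raise ValueError("pre-edge center must lie below the edge energy")
        object.__setattr__(self, "features", tuple(self.features))


#: Bound Co²⁺–protein complex: pre-edge 1s→3d feature near 7710 eV, strong
#: white line, shape resonance.
BOUND_PROFILE = ReferenceProfile(
    e0=7720.0,
    edge_width=2.0,
    pre_edge=GaussianFeature(7710.0, 0.05, 1.5),
    features=(GaussianFeature(7727.0, 0.45, 4.0), GaussianFeature(7760.0, 0.08, 9.0)),
    post_slope=-2.0e-4,
)

#: Free aquo Co²⁺ (buffer): slightly shifted edge, weaker pre-edge, different
#: white-line shape — distinct enough for a well-conditioned two-component fit.
BUFFER_PROFILE = ReferenceProfile(
    e0=7721.5,
    edge_width=2.6,
    pre_edge=GaussianFeature(7709.5, 0.03, 1.5),
    features=(GaussianFeature(7725.0, 0.30, 6.0), GaussianFeature(7751.0, 0.05, 8.0)),
    post_slope=-1.0e-4,
)


def default_energy_grid(e0: float = 7720.0, step: float = 0.5,
                        below: float = 200.0, above: float = 300.0) -> np.ndarray:
    """Uniform energy grid spanning [e0 − below, e0 + above] eV."""
    return np.arange(e0 - below, e0 + above + 0.5 * step, step)


def make_reference_xanes(profile: ReferenceProfile, grid: np.ndarray,
                         label: str = "") -> Spectrum:
    """Deterministic reference XANES on ``grid``.

    μ(E) = arctan unit step + pre-edge Gaussian + post-edge Gaussian features
    + a linear post-edge slope that vanishes below the edge.  μ(E₀) = 0.5 for
    a featureless profile.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] > profile.e0 - 50.0 or grid[-1] < profile.e0 + 50.0:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] does not cover the edge at {profile.e0} eV"
        )
    step = 0.5 + np.arctan((grid - profile.e0) / profile.edge_width) / np.pi
    mu = step.copy()
    if profile.pre_edge is not None:
        mu += profile.pre_edge(grid)
    for feat in profile.features:
        mu += feat(grid)
    # slope rides on the step so the pre-edge region stays flat at zero
    mu += profile.post_slope * (grid - profile.e0) * step
    return Spectrum(grid, mu, label=label)


def make_mixture(components: Sequence[Spectrum], fractions: Sequence[float],
                 noise_sd: float = 0.0, seed: int | None = None,
                 label: str = "mixture") -> Spectrum:
    """Point-by-point linear combination of spectra on a shared grid.

    μ_mix(E) = Σ f_i μ_i(E) (+ seeded Gaussian noise).  Fractions must be
    non-negative and sum to 1 within 1e-9.
    """
    if not components:
        raise ValueError("need at least one component")
    fr = np.asarray(fractions, dtype=float)
    if len(fr) != len(components):
        raise ValueError("one fraction per component required")
    if np.any(fr < 0):
        raise ValueError("fractions must be non-negative")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fr.sum()!r}")
    grid = components[0].energies
    for c in components[1:]:
        if len(c.energies) != len(grid) or not np.array_equal(c.energies, grid):
            raise ValueError("all components must share an identical energy grid")
    mu = sum(f * c.mu for f, c in zip(fr, components))
    if noise_sd > 0:
        if seed is None:
            raise ValueError("a seed is required when noise_sd > 0")
        mu = mu + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(grid))
    return Spectrum(grid.copy(), mu, label=label)


# octahedral ligand axes, assignment order fixed for reproducible fixtures
_OCTAHEDRAL_AXES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)


def make_site_geometry(shells: Sequence[tuple[int, float]],
                       absorber: str = "Co",
                       shell_res_names: Sequence[str] | None = None) -> list[AtomRecord]:
    """Place oxygen ligands of an octahedral site on ±x, ±y, ±z axes.

    Shells are assigned axes in order of descending ligand count (ties keep
    input order), filling +x, −x, +y, −y, +z, −z; the absorber sits at the
    origin.  ``shell_res_names`` optionally labels each shell's residue
    (rigid-group carrier), defaulting to LIG.
    """
    total = sum(int(n) for n, _ in shells)
    if total > 6:
        raise ValueError(f"octahedral placement supports at most 6 ligands, got {total}")
    if shell_res_names is None:
        shell_res_names = ["LIG"] * len(shells)
    if len(shell_res_names) != len(shells):
        raise ValueError("one residue name per shell required")
    atoms = [AtomRecord(absorber, np.zeros(3), res_name=absorber.upper(), res_seq=1,
                        atom_name=absorber.upper())]
    order = sorted(range(len(shells)), key=lambda i: (-shells[i][0], i))
    axis_idx = 0
    serial = 1
    for i in order:
        count, dist = shells[i]
        for _ in range(int(count)):
            pos = _OCTAHEDRAL_AXES[axis_idx] * float(dist)
            serial += 1
            atoms.append(
                AtomRecord("O", pos, res_name=shell_res_names[i], res_seq=i + 2,
                           atom_name=f"O{serial}")
            )
            axis_idx += 1
    return atoms


def default_background_points(e0: float = 7720.0) -> list[tuple[float, float]]:
    """Control points of a realistic smooth μ background with an edge jump.

    Below the edge: a nearly flat pre-edge absorption around 0.09.  Above:
    the atomic absorption jumps to ~1.2 and decays exponentially on a
    ~250 eV scale — the smooth μ₀ that background removal must take out.
    Points are sampled densely enough that the interpolating cubic spline
    carries no ringing beyond the edge-jump interval itself.
    """
    pre = [(e0 + de, 0.090 + 2.0e-5 * de) for de in (-220.0, -120.0, -60.0, -30.0, -5.0)]
    post_offsets = (5.0, 30.0, 60.0, 100.0, 150.0, 220.0, 300.0, 400.0, 520.0, 650.0)
    post = [(e0 + de, 0.95 + 0.25 * np.exp(-de / 250.0)) for de in post_offsets]
    return pre + post


def make_exafs_spectrum(model, table, grid: np.ndarray,
                        bkg_points: Sequence[tuple[float, float]] | None = None,
                        noise_sd: float = 0.0, seed: int | None = None,
                        label: str = "exafs") -> Spectrum:
    """Raw μ(E) with EXAFS oscillations from a coordination-site model.

    μ(E) = bkg(E)·[1 + χ(k(E))] above the edge and μ(E) = bkg(E) below,
    where bkg is a monotone (shape-preserving) cubic spline through ``bkg_points`` and χ comes from
    :func:`xasmelt.exafs.forward_chi` evaluated with the model's own Fermi
    shift folded in (the generated signal carries the true ΔE_F; extraction
    assumes zero, so the fit must recover it).
    """
    from .exafs import energy_to_k, forward_chi  # local import avoids a cycle

    grid = np.asarray(grid, dtype=float)
    e0 = model.e0
    if grid[-1] < e0 + 500.0:
        raise ValueError("grid must extend at least 500 eV above the edge")
    if bkg_points is None:
        bkg_points = default_background_points(e0)
    pts = np.asarray(bkg_points, dtype=float)
    # shape-preserving cubic: an interpolant through an edge jump must not ring
    spline = PchipInterpolator(pts[:, 0], pts[:, 1])
    bkg = spline(grid)
    above = grid > e0
    if np.any(bkg[above] <= 0):
        raise ValueError("background must be positive above the edge")
    mu = bkg.copy()
    if model.shells:
        # χ only exists where the shifted photoelectron energy is positive
        valid = grid > e0 + max(0.0, -model.delta_ef) + 1e-9
        k = energy_to_k(grid[valid], e0)
        chi = forward_chi(model, table, k).chi
        mu[valid] = bkg[valid] * (1.0 + chi)
    if noise_sd > 0:
        if seed is None:
            raise ValueError("a seed is required when noise_sd > 0")
        mu = mu + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(grid))
    return Spectrum(grid, mu, label=label)


@dataclass(frozen=True)
class TransitionModel:
    """One two-state unfolding transition (van't Hoff, ΔCp = 0).

    ``tm`` in °C, ``dh`` (van't Hoff enthalpy) in kJ/mol, ``amplitude`` is
    this transition's fraction of the total ellipticity change; baselines are
    (intercept, slope) pairs in deg·cm²·dmol⁻¹ and per-°C.
    """

    tm: float
    dh: float = 300.0
    amplitude: float = 1.0
    native_baseline: tuple[float, float] = (-20000.0, 0.0)
    unfolded_baseline: tuple[float, float] = (-2000.0, 0.0)

    def __post_init__(self):
        if self.dh <= 0:
            raise ValueError("van't Hoff enthalpy must be positive")
        if not (0.0 < self.amplitude <= 1.0):
            raise ValueError("amplitude fraction must be in (0, 1]")

    def unfolded_fraction(self, t_celsius: np.ndarray) -> np.ndarray:
        """fU(T) = K/(1+K), K = exp[−(ΔH/R)·(1/T − 1/Tm)] in kelvin."""
        t_k = np.asarray(t_celsius, dtype=float) + 273.15
        tm_k = self.tm + 273.15
        ln_k = -(self.dh / R_GAS) * (1.0 / t_k - 1.0 / tm_k)
        # K/(1+K) computed stably via the logistic function
        return 1.0 / (1.0 + np.exp(-ln_k))


def make_melting_curve(transitions: Sequence[TransitionModel], grid: np.ndarray,
                       noise_sd: float = 0.0, seed: int | None = None,
                       label: str = "") -> MeltingCurve:
    """Superpose 1–2 two-state transitions into a Θ₂₂₂(T) scan.

    Θ(T) = Σ_j a_j·[θN_j(T) + (θU_j(T) − θN_j(T))·fU_j(T)] + seeded noise.
    Amplitude fractions must sum to 1; the grid follows the measurement
    protocol (20–95 °C, 0.5 °C steps).
    """
    if not transitions:
        raise ValueError("at least one transition is required")
    if len(transitions) > 2:
        raise ValueError("at most two transitions are supported")
    amps = sum(t.amplitude for t in transitions)
    if abs(amps - 1.0) > 1e-9:
        raise ValueError(f"amplitude fractions must sum to 1, got {amps}")
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 20.0 - 1e-9 or grid[-1] > 95.0 + 1e-9:
        raise ValueError("temperature grid must lie within [20, 95] °C")
    theta = np.zeros_like(grid)
    for tr in transitions:
        n = tr.native_baseline[0] + tr.native_baseline[1] * grid
        u = tr.unfolded_baseline[0] + tr.unfolded_baseline[1] * grid
        theta += tr.amplitude * (n + (u - n) * tr.unfolded_fraction(grid))
    if noise_sd > 0:
        if seed is None:
            raise ValueError("a seed is required when noise_sd > 0")
        theta = theta + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(grid))
    return MeltingCurve(grid, theta, label=label)
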