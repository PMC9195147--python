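"""EXAFS: χ(k) extraction, single-scattering forward model, shell grouping,
and constrained shell refinement.

The forward model is the standard single-scattering EXAFS equation

    χ(k) = S₀² Σᵢ Nᵢ f(k′) / (k′ Rᵢ²) · exp(−2k′²σᵢ²) · exp(−2Rᵢ/λ(k′))
           · sin(2k′Rᵢ + φ(k′)),   k′ = sqrt(k² + c·ΔE_F)

with c = 2mₑ/ħ² = 0.262468 eV⁻¹ Å⁻², where the Fermi-energy shift ΔE_F
re-references the photoelectron energy zero.  Background removal follows the
AUTOBK idea: a cubic B-spline whose coefficients minimize the Fourier
magnitude of the k-weighted residual below ``rbkg``, so the spline absorbs
everything smoother than the first coordination shell.

Refinement is a bounded trust-region least squares over shell radii and
ΔE_F; shells sharing a rigid-group label move with one common radial offset,
the distance-fit reading of a rigid-body constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline, CubicSpline
from scipy.optimize import least_squares

from .types import AtomRecord
from .xanes import NormalizedXanes

__all__ = [
    "K_CONV",
    "ExafsSignal",
    "ScatteringShell",
    "MetalSiteModel",
    "ScatterTable",
    "FitResult",
    "default_oxygen_table",
    "energy_to_k",
    "extract_chi",
    "forward_chi",
    "excise_sphere",
    "group_shells",
    "refine",
    "r_factor",
]

#: 2mₑ/ħ² in eV⁻¹ Å⁻²: k[Å⁻¹] = sqrt(K_CONV · (E − E₀)[eV]).
K_CONV = 0.262468

DEFAULT_K_RANGE = (3.0, 12.0)
DEFAULT_K_WEIGHT = 2
DEFAULT_SIGMA2 = 0.003  # Å², held fixed unless explicitly freed


def energy_to_k(energies, e0: float, delta_ef: float = 0.0) -> np.ndarray:
    """Photoelectron wavenumber k for E ≥ E₀ + ΔE_F (clipped at zero)."""
    e = np.asarray(energies, dtype=float)
    return np.sqrt(np.clip(K_CONV * (e - e0 - delta_ef), 0.0, None))


@dataclass(frozen=True)
class ExafsSignal:
    """χ(k) on a strictly increasing k grid; ``k_weight`` records any k^w
    weighting already applied (0 for plain χ)."""

    k: np.ndarray
    chi: np.ndarray
    k_weight: int = 0

    def __post_init__(self):
        k = np.asarray(self.k, dtype=float)
        chi = np.asarray(self.chi, dtype=float)
        if len(k) != len(chi):
            raise ValueError("k and chi must have equal length")
        if np.any(k < 0) or np.any(np.diff(k) <= 0):
            raise ValueError("k must be non-negative and strictly increasing")
        if not 0 <= int(self.k_weight) <= 3:
            raise ValueError("k_weight must be an integer in 0..3")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "chi", chi)


@dataclass(frozen=True)
class ScatteringShell:
    """One coordination shell: N scatterers of one element at distance R (Å)
    with Debye–Waller factor sigma2 (Å²)."""

    n: int
    r: float
    sigma2: float = DEFAULT_SIGMA2
    element: str = "O"

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("coordination number must be a positive integer")
        if not (1.0 < self.r < 6.0):
            raise ValueError(f"shell radius must lie in (1, 6) Å, got {self.r}")
        if not (0.0 <= self.sigma2 <= 0.05):
            raise ValueError(f"sigma2 must lie in [0, 0.05] Å², got {self.sigma2}")


@dataclass(frozen=True)
class MetalSiteModel:
    """Absorber + shells + the global EXAFS parameters E₀, ΔE_F, S₀².

    ``rigid_groups`` maps shell index → group label; shells in one group share
    a single radial offset during refinement.
    """

    absorber: str = "Co"
    e0: float = 7720.0
    delta_ef: float = 0.0
    s02: float = 0.9
    shells: tuple = ()
    rigid_groups: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.5 < self.s02 <= 1.1):
            raise ValueError(f"S0² must lie in (0.5, 1.1], got {self.s02}")
        if abs(self.delta_ef) > 15.0:
            raise ValueError(f"|ΔE_F| must be ≤ 15 eV, got {self.delta_ef}")
        object.__setattr__(self, "shells", tuple(self.shells))

    def group_of(self, i: int) -> str:
        return self.rigid_groups.get(i, f"shell{i}")


@dataclass(frozen=True)
class ScatterTable:
    """Backscattering amplitude f(k), phase φ(k) (total, rad) and mean free
    path λ(k) (Å) sampled on a k grid; interpolated linearly in between."""

    k: np.ndarray
    f: np.ndarray
    phase: np.ndarray
    lam: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        k = np.asarray(self.k, dtype=float)
        for name in ("f", "phase", "lam"):
            v = np.asarray(getattr(self, name), dtype=float)
            if len(v) != len(k):
                raise ValueError(f"{name} must match the k grid length")
            object.__setattr__(self, name, v)
        if np.any(self.f <= 0):
            raise ValueError("amplitude f(k) must be positive")
        object.__setattr__(self, "k", k)

    def interp(self, k: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if k.min() < self.k[0] - 1e-9 or k.max() > self.k[-1] + 1e-9:
            raise ValueError(
                f"k range [{k.min():.2f}, {k.max():.2f}] outside table domain "
                f"[{self.k[0]:.2f}, {self.k[-1]:.2f}]"
            )
        return (np.interp(k, self.k, self.f),
                np.interp(k, self.k, self.phase),
                np.interp(k, self.k, self.lam))


def default_oxygen_table(k_max: float = 20.0) -> ScatterTable:
    """Synthetic oxygen backscattering table, shared by generator and fitter.

    f(k) = 0.90·exp(−0.15k), φ(k) = π − 0.90k, λ(k) = 4 + 0.8k.  This is a
    smooth O-like parameterization chosen for self-consistent parameter
    recovery, not a physical phase-shift calculation.
    """
    k = np.linspace(0.0, k_max, 401)
    return ScatterTable(k, 0.90 * np.exp(-0.15 * k), np.pi - 0.90 * k,
                        4.0 + 0.8 * k, provenance="synthetic-oxygen-default")


def forward_chi(m: MetalSiteModel, t: ScatterTable, kgrid) -> ExafsSignal:
    """Evaluate the single-scattering EXAFS equation on ``kgrid``."""
    k = np.asarray(kgrid, dtype=float)
    k2 = k**2 + K_CONV * m.delta_ef
    if np.any(k2 < 0):
        bad = k[k2 < 0]
        raise ValueError(
            f"Fermi shift {m.delta_ef} eV makes k' imaginary for "
            f"k in [{bad.min():.3f}, {bad.max():.3f}]"
        )
    kp = np.sqrt(k2)
    chi = np.zeros_like(k)
    if m.shells:
        kp_safe = np.where(kp > 1e-9, kp, 1e-9)
        f, phase, lam = t.interp(kp)
        for shell in m.shells:
            amp = (m.s02 * shell.n * f / (kp_safe * shell.r**2)
                   * np.exp(-2.0 * kp**2 * shell.sigma2)
                   * np.exp(-2.0 * shell.r / lam))
            chi += amp * np.sin(2.0 * kp * shell.r + phase)
    return ExafsSignal(k, chi, k_weight=0)


def extract_chi(n: NormalizedXanes, rbkg: float = 1.0, k_weight: int = DEFAULT_K_WEIGHT,
                dk: float = 0.05, k_min: float = 1.5) -> ExafsSignal:
    """AUTOBK-style background removal: χ(k) from a normalized spectrum.

    The unflattened step-normalized μ is resampled on a uniform k grid from
    ``k_min`` (just past the edge jump, which no smooth spline can follow);
    a cubic B-spline with ``floor(2·Δk·rbkg/π) + 1`` coefficients is fitted
    by linear least squares so as to minimize the Fourier-transform magnitude
    of the k-weighted residual at distances below ``rbkg`` — the spline soaks
    up everything smoother than the first coordination shell.  A weak
    data-anchoring term regularizes spline directions the short-distance
    Fourier window cannot see.  χ = μ − spline (the edge step is already 1).
    """
    if rbkg <= 0:
        raise ValueError("rbkg must be positive")
    e, mu, e0 = n.energies, n.unflat_mu, n.e0
    if e[-1] < e0 + 400.0:
        raise ValueError("data must extend at least 400 eV above the edge")
    k_max = float(np.sqrt(K_CONV * (e[-1] - e0)))
    k = np.arange(k_min, k_max, dk)
    mu_k = np.interp(e0 + k**2 / K_CONV, e, mu)

    n_coef = int(np.floor(2.0 * (k[-1] - k[0]) * rbkg / np.pi)) + 1
    n_coef = max(n_coef, 5)  # a cubic spline needs >= 5 coefficients
    degree = 3
    n_interior = n_coef - degree - 1
    interior = np.linspace(k[0], k[-1], n_interior + 2)[1:-1] if n_interior > 0 else []
    knots = np.concatenate([[k[0]] * (degree + 1), interior, [k[-1]] * (degree + 1)])
    basis = BSpline.design_matrix(k, knots, degree).toarray()

    # FT rows: residual -> complex FT sampled on R in [0, rbkg]
    r_grid = np.linspace(0.0, rbkg, 32)
    w = k**k_weight
    phase = np.exp(2j * np.outer(r_grid, k)) * (w * dk)
    ft = np.vstack([phase.real, phase.imag])
    anchor = 0.05 * (w * dk)[:, None] * basis  # regularizer: track the data weakly
    a_mat = np.vstack([ft @ basis, anchor])
    rhs = np.concatenate([ft @ mu_k, 0.05 * (w * dk) * mu_k])
    coef, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    chi = mu_k - basis @ coef
    return ExafsSignal(k, chi, k_weight=0)


def excise_sphere(atoms: list[AtomRecord], center_element: str, radius: float) -> list[AtomRecord]:
    """Keep atoms within ``radius`` Å (closed boundary) of the unique atom of
    ``center_element``; the center itself is always retained."""
    centers = [a for a in atoms if a.element.capitalize() == center_element.capitalize()]
    if len(centers) != 1:
        raise ValueError(
            f"expected exactly one {center_element} atom, found {len(centers)}"
        )
    c = centers[0].coords
    return [a for a in atoms if np.linalg.norm(a.coords - c) <= radius + 1e-12]


def group_shells(site: list[AtomRecord], absorber: str = "Co",
                 tol: float = 0.1, e0: float = 7720.0,
                 sigma2: float = DEFAULT_SIGMA2, s02: float = 0.9) -> MetalSiteModel:
    """Cluster ligand distances into coordination shells.

    Distances are sorted ascending and greedily clustered: a new shell starts
    when a distance exceeds the running shell mean by more than ``tol`` Å.
    Shell R is the member mean, N the member count; rigid-group labels are
    carried from residue identity (name + number) when unanimous.
    """
    centers = [a for a in site if a.element.capitalize() == absorber.capitalize()]
    if len(centers) != 1:
        raise ValueError(f"expected exactly one {absorber} absorber, found {len(centers)}")
    ligands = [a for a in site if a is not centers[0]]
    if not ligands:
        raise ValueError("site contains no ligand atoms")
    c = centers[0].coords
    dists = np.array([np.linalg.norm(a.coords - c) for a in ligands])
    order = np.argsort(dists, kind="stable")

    shells: list[list[int]] = [[order[0]]]
    for idx in order[1:]:
        current = shells[-1]
        mean = dists[current].mean()
        if dists[idx] - mean > tol:
            shells.append([idx])
        else:
            current.append(idx)

    shell_objs = []
    groups: dict[int, str] = {}
    for i, members in enumerate(shells):
        r = float(dists[members].mean())
        elem = ligands[members[0]].element
        shell_objs.append(ScatteringShell(n=len(members), r=r, sigma2=sigma2, element=elem))
        labels = {f"{ligands[j].res_name}{ligands[j].res_seq}" for j in members}
        groups[i] = labels.pop() if len(labels) == 1 else f"shell{i}"
    return MetalSiteModel(absorber=centers[0].element, e0=e0, s02=s02,
                          shells=tuple(shell_objs), rigid_groups=groups)


def r_factor(obs: ExafsSignal, model: ExafsSignal, k_weight: int = DEFAULT_K_WEIGHT) -> float:
    """Misfit in percent: 100·Σ|k^w(χ_obs − χ_mod)| / Σ|k^w·χ_obs|."""
    if len(obs.k) != len(model.k) or not np.allclose(obs.k, model.k):
        raise ValueError("observed and model signals must share a common k grid")
    w = obs.k**k_weight
    denom = np.sum(np.abs(w * obs.chi))
    if denom == 0:
        raise ValueError("observed signal is identically zero")
    return float(100.0 * np.sum(np.abs(w * (obs.chi - model.chi))) / denom)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a constrained refinement."""

    model: MetalSiteModel
    deltas: dict
    r_factor: float
    k_range: tuple[float, float]
    converged: bool

    def __post_init__(self):
        if self.r_factor < 0:
            raise ValueError("R-factor must be non-negative")


def refine(obs: ExafsSignal, m0: MetalSiteModel, t: ScatterTable,
           free: tuple[str, ...] = ("radii", "ef"),
           k_range: tuple[float, float] = DEFAULT_K_RANGE,
           k_weight: int = DEFAULT_K_WEIGHT) -> FitResult:
    """Bounded least-squares refinement of shell radii and/or ΔE_F.

    ``free`` selects the released parameters: "radii" adds one radial offset
    per rigid group (shells sharing a group label move together), "ef" adds
    the Fermi shift.  The cost is the k-weighted χ misfit over ``k_range``;
    bounds keep radii in (1, 6) Å and |ΔE_F| ≤ 15 eV.
    """
    if not free:
        raise ValueError("free-parameter mask must not be empty")
    unknown = set(free) - {"radii", "ef"}
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if not m0.shells:
        raise ValueError("model must contain at least one shell to refine")
    mask = (obs.k >= k_range[0]) & (obs.k <= k_range[1])
    if mask.sum() < 8:
        raise ValueError("observed signal does not cover the fitting k range")
    kfit = obs.k[mask]
    chi_obs = obs.chi[mask]
    w = kfit**k_weight

    fit_radii = "radii" in free
    fit_ef = "ef" in free
    group_labels = sorted({m0.group_of(i) for i in range(len(m0.shells))}) if fit_radii else []
    n_off = len(group_labels)

    def build(params: np.ndarray) -> MetalSiteModel:
        offsets = dict(zip(group_labels, params[:n_off]))
        ef = params[n_off] if fit_ef else m0.delta_ef
        shells = tuple(
            replace(s, r=s.r + offsets.get(m0.group_of(i), 0.0))
            for i, s in enumerate(m0.shells)
        )
        return replace(m0, shells=shells, delta_ef=float(ef))

    def resid(params: np.ndarray) -> np.ndarray:
        model = build(params)
        chi_mod = forward_chi(model, t, kfit).chi
        out = w * (chi_obs - chi_mod)
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite residuals during refinement")
        return out

    lower, upper, x0 = [], [], []
    for label in group_labels:
        radii = [s.r for i, s in enumerate(m0.shells) if m0.group_of(i) == label]
        lower.append(1.0 + 1e-6 - min(radii))
        upper.append(6.0 - 1e-6 - max(radii))
        x0.append(0.0)
    if fit_ef:
        lower.append(-15.0)
        upper.append(15.0)
        x0.append(m0.delta_ef)

    sol = least_squares(resid, np.asarray(x0), bounds=(lower, upper),
                        method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-12)
    refined = build(sol.x)
    chi_mod = forward_chi(refined, t, kfit).chi
    rf = r_factor(ExafsSignal(kfit, chi_obs), ExafsSignal(kfit, chi_mod), k_weight)
    deltas: dict = {}
    for j, label in enumerate(group_labels):
        deltas[f"dr[{label}]"] = float(sol.x[j])
    if fit_ef:
        deltas["delta_ef"] = float(sol.x[n_off] - m0.delta_ef)
    return FitResult(model=refined, deltas=deltas, r_factor=rf,
                     k_range=(float(kfit[0]), float(kfit[-1])),
                     converged=bool(sol.status > 0))
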