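"""Core data containers shared by every stage of the pipeline.

All containers are frozen dataclasses around numpy arrays.  Invariants are
enforced at construction time so downstream code can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "MeltingCurve",
    "AtomRecord",
    "StabilityRecord",
    "MIN_POINTS",
]

#: Minimum number of points for a spectrum / melting curve to be meaningful.
MIN_POINTS = 16


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_xy(x: np.ndarray, y: np.ndarray, xname: str) -> None:
    if len(x) != len(y):
        raise ValueError(f"{xname} and ordinate differ in length: {len(x)} vs {len(y)}")
    if len(x) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {len(x)}")
    if np.any(np.diff(x) <= 0):
        raise ValueError(f"{xname} must be strictly increasing")


@dataclass(frozen=True)
class Spectrum:
    """Raw X-ray absorption spectrum: μ(E).

    Parameters
    ----------
    energies : array of float
        Photon energies in eV, strictly increasing.
    mu : array of float
        Absorption coefficient, arbitrary units, same length as ``energies``.
    label : str
        Free-text sample label.
    """

    energies: np.ndarray
    mu: np.ndarray
    label: str = ""

    def __post_init__(self):
        e = _as_float_array(self.energies, "energies")
        m = _as_float_array(self.mu, "mu")
        _check_xy(e, m, "energies")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu", m)

    def __len__(self) -> int:
        return len(self.energies)

    def with_mu(self, mu: np.ndarray, label: str | None = None) -> "Spectrum":
        return Spectrum(self.energies.copy(), mu, self.label if label is None else label)


@dataclass(frozen=True)
class MeltingCurve:
    """CD thermal scan: mean residue ellipticity at 222 nm vs. temperature.

    Temperatures are in °C, strictly increasing, nominally on a 0.5 °C grid;
    ``theta222`` is in deg·cm²·dmol⁻¹.
    """

    temperatures: np.ndarray
    theta222: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = _as_float_array(self.temperatures, "temperatures")
        y = _as_float_array(self.theta222, "theta222")
        _check_xy(t, y, "temperatures")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "theta222", y)

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class AtomRecord:
    """A single atom of a metal-site model (orthogonal Å coordinates)."""

    element: str
    coords: np.ndarray
    res_name: str = ""
    res_seq: int = 0
    atom_name: str = ""

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got shape {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords contain non-finite values")
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "element", self.element.strip().capitalize())


@dataclass(frozen=True)
class StabilityRecord:
    """Per-sample summary joining melting and XANES outputs.

    ``fragment`` is the frataxin construct ("81-210" or "90-210");
    ``equivalents`` is the molar Co²⁺:protein ratio ("none", "0.3", "0.8",
    "1.6"); ``tms`` holds one or two melting temperatures in °C, ascending;
    ``delta_tm`` is Tm(with metal) − Tm(metal-free partner) using the first
    (lowest) transition of each, so destabilization is negative.
    """

    name: str
    fragment: str
    equivalents: str
    tms: tuple = ()
    delta_tm: float | None = None
    bound_fraction: float | None = None

    ALLOWED_EQUIV = ("none", "0.3", "0.8", "1.6")
    ALLOWED_FRAGMENTS = ("81-210", "90-210")

    def __post_init__(self):
        if self.equivalents not in self.ALLOWED_EQUIV:
            raise ValueError(
                f"equivalents must be one of {self.ALLOWED_EQUIV}, got {self.equivalents!r}"
            )
        if self.fragment not in self.ALLOWED_FRAGMENTS:
            raise ValueError(
                f"fragment must be one of {self.ALLOWED_FRAGMENTS}, got {self.fragment!r}"
            )
        object.__setattr__(self, "tms", tuple(float(t) for t in self.tms))
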