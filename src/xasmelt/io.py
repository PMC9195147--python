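"""File I/O: two-column XY text spectra and melts, PDB sites, TSV reports.

The XY dialect is whitespace-delimited ASCII with ``#`` comment lines and a
decimal point (no locale handling) — the convention of typical beamline and
spectropolarimeter exports.  Rows are sorted by abscissa and exact duplicate
abscissae are averaged (multi-scan merges produce duplicates).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import gemmi

from .types import MIN_POINTS, AtomRecord, MeltingCurve, Spectrum, StabilityRecord

__all__ = ["read_xy", "write_xy", "read_site_pdb", "write_report", "format_tms"]


class ParseError(ValueError):
    """A text input could not be parsed; the message names the line."""


def _parse_xy_text(path: Path) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            parts = stripped.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    return np.asarray(xs), np.asarray(ys)


def _sort_and_merge(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # average exact-duplicate abscissae
    uniq, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    if len(uniq) != len(x):
        sums = np.zeros(len(uniq))
        np.add.at(sums, inverse, y)
        y = sums / counts
        x = uniq
    return x, y


def read_xy(path, kind: str = "spectrum") -> Spectrum | MeltingCurve:
    """Read a two-column XY file as a :class:`Spectrum` or :class:`MeltingCurve`.

    Only the first two numeric columns are used.  ``kind`` selects the
    returned type: ``"spectrum"`` (energy eV / μ) or ``"melt"``
    (temperature °C / Θ₂₂₂).
    """
    path = Path(path)
    if kind not in ("spectrum", "melt"):
        raise ValueError(f"kind must be 'spectrum' or 'melt', got {kind!r}")
    x, y = _parse_xy_text(path)
    if len(x) < MIN_POINTS:
        raise ValueError(f"{path}: need at least {MIN_POINTS} data rows, got {len(x)}")
    x, y = _sort_and_merge(x, y)
    label = path.stem
    if kind == "spectrum":
        return Spectrum(x, y, label=label)
    return MeltingCurve(x, y, label=label)


def write_xy(obj: Spectrum | MeltingCurve, path) -> None:
    """Write a spectrum or melting curve back to the two-column dialect."""
    if isinstance(obj, Spectrum):
        x, y, header = obj.energies, obj.mu, "# energy_eV  mu"
    else:
        x, y, header = obj.temperatures, obj.theta222, "# temperature_C  theta222"
    with open(path, "w") as fh:
        fh.write(f"{header}  # {obj.label}\n")
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.10g} {yi:.10g}\n")


def read_site_pdb(path) -> list[AtomRecord]:
    """Read ATOM/HETATM records of a PDB file as a flat list of atoms.

    Element symbols come from the element columns when present; gemmi's
    atom-name fallback covers records that lack them.  Coordinates are taken
    as orthogonal Å, no symmetry expansion.
    """
    structure = gemmi.read_pdb(str(path))
    records: list[AtomRecord] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    records.append(
                        AtomRecord(
                            element=atom.element.name,
                            coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            res_name=residue.name.strip(),
                            res_seq=residue.seqid.num,
                            atom_name=atom.name.strip(),
                        )
                    )
        break  # single-model PDBs only; extra models are out of scope
    if not records:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return records


def write_site_pdb(atoms: Sequence[AtomRecord], path) -> None:
    """Write atoms as minimal HETATM records (inverse of :func:`read_site_pdb`)."""
    with open(path, "w") as fh:
        for i, a in enumerate(atoms, start=1):
            name = (a.atom_name or a.element)[:4]
            fh.write(
                "HETATM%5d %-4s %-3s A%4d    %8.3f%8.3f%8.3f  1.00  0.00          %2s\n"
                % (i, name, (a.res_name or "LIG")[:3], a.res_seq or i,
                   a.coords[0], a.coords[1], a.coords[2], a.element.upper())
            )
        fh.write("END\n")


def format_tms(tms: Sequence[float]) -> str:
    """Render one or two melting temperatures, e.g. ``"Tm1=43.0; Tm2=59.0"``."""
    if len(tms) == 1:
        return f"{tms[0]:.1f}"
    return "; ".join(f"Tm{i}={t:.1f}" for i, t in enumerate(tms, start=1))


def write_report(records: Sequence[StabilityRecord], path) -> None:
    """Write the joint stability report as a TSV table, one row per sample."""
    if not records:
        raise ValueError("cannot write a report from an empty record list")
    cols = ["name", "fragment", "equivalents", "tm_C", "delta_tm_C", "bound_fraction"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.name,
                r.fragment,
                r.equivalents,
                format_tms(r.tms) if r.tms else "NA",
                f"{r.delta_tm:.1f}" if r.delta_tm is not None else "NA",
                f"{r.bound_fraction:.3f}" if r.bound_fraction is not None else "NA",
            ]
            fh.write("\t".join(row) + "\n")
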