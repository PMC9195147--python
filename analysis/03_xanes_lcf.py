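#!/usr/bin/env python
"""Quantify bound vs. free Co²⁺ by XANES linear-combination fitting.

Reads the simulated long-fragment spectrum (a 43/57 mixture of the
bound-complex and buffer references), normalizes all three spectra, fits the
mixing coefficient, and writes the fractions plus the difference spectrum.
The headline number: ~43% of the metal is protein-bound, ~57% stays free in
solution.
"""

from pathlib import Path

from xasmelt import io as xio
from xasmelt import xanes

SIM = Path("results/sim/xas")
target = xanes.normalize(xio.read_xy(SIM / "wt_81_0.8.xy"))
bound = xanes.normalize(xio.read_xy(SIM / "bound.xy"))
buffer_ = xanes.normalize(xio.read_xy(SIM / "buffer.xy"))

res = xanes.lcf(target, bound, buffer_)
diff = xanes.difference_spectrum(target, res, bound, buffer_)
xio.write_xy(diff, Path("results/lcf_difference.xy"))

peak = xanes.pre_edge_peak(bound)

out = Path("results/xanes_lcf.tsv")
with open(out, "w") as fh:
    fh.write("quantity\tvalue\n")
    fh.write(f"bound_fraction\t{res.fractions[0]:.4f}\n")
    fh.write(f"free_fraction\t{res.fractions[1]:.4f}\n")
    fh.write(f"rms_residual\t{res.residual:.6g}\n")
    fh.write(f"pre_edge_center_eV\t{peak.center:.2f}\n")

print(f"bound fraction  = {res.fractions[0]:.3f}  (generating truth 0.43)")
print(f"free fraction   = {res.fractions[1]:.3f}")
print(f"rms residual    = {res.residual:.2e}")
print(f"pre-edge 1s->3d center = {peak.center:.1f} eV (octahedral-site marker)")
print(f"wrote {out} and results/lcf_difference.xy")
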