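#!/usr/bin/env python
"""Generate the full synthetic input set for the study.

Writes, under results/sim/: one CD thermal scan per sample (wild type and
the D104G/Y123S/S161I variants, with and without Co²⁺), the bound-complex
and free-ion XANES references and their 43/57 mixture, the raw EXAFS μ(E)
of the octahedral Co–O site, and the 7-atom site geometry as PDB.
"""

from pathlib import Path

import numpy as np

from xasmelt import io as xio
from xasmelt import synth
from xasmelt.acceptance import table_site_model
from xasmelt.exafs import default_oxygen_table
from xasmelt.pipeline import DEMO_CONFIG

OUT = Path("results/sim")
XAS = OUT / "xas"
XAS.mkdir(parents=True, exist_ok=True)
SEED = 0

melt_cfg = DEMO_CONFIG["melting"]
grid_t = np.arange(20.0, 95.25, 0.5)
for i, sample in enumerate(melt_cfg["samples"]):
    transitions = [
        synth.TransitionModel(tm=float(tm), dh=float(dh), amplitude=1.0 / len(sample["tms"]))
        for tm, dh in zip(sample["tms"], sample["dh"])
    ]
    curve = synth.make_melting_curve(transitions, grid_t, label=sample["name"])
    xio.write_xy(curve, OUT / f"{sample['name']}.xy")
print(f"wrote {len(melt_cfg['samples'])} melting curves (20-95 C, 0.5 C grid)")

grid_e = synth.default_energy_grid()
bound = synth.make_reference_xanes(synth.BOUND_PROFILE, grid_e, label="bound")
buffer_ = synth.make_reference_xanes(synth.BUFFER_PROFILE, grid_e, label="buffer")
mix = synth.make_mixture([bound, buffer_], [0.43, 0.57], label="wt_81_0.8")
for spec in (bound, buffer_, mix):
    xio.write_xy(spec, XAS / f"{spec.label}.xy")
print("wrote XANES references and the 43/57 bound/free mixture")

site_model = table_site_model()
atoms = synth.make_site_geometry([(4, 2.02), (1, 2.21), (1, 1.85)],
                                 shell_res_names=["MIX", "GLU", "HOH"])
xio.write_site_pdb(atoms, XAS / "site.pdb")
mu_grid = np.arange(site_model.e0 - 200.0, site_model.e0 + 660.0, 0.5)
exafs_mu = synth.make_exafs_spectrum(site_model, default_oxygen_table(), mu_grid,
                                     label="co_site_mu")
xio.write_xy(exafs_mu, XAS / "co_site_mu.xy")
print("wrote octahedral Co-O site (PDB) and its EXAFS-bearing mu(E)")
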