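#!/usr/bin/env python
"""Combine the three flexibility measures into one site-resolved table.

Joins, per residue and isoform, the CPMG ΔRex amplitude and class, the HDX
exchange rate with its censoring flag, and the ensemble Cα B-factor: the
per-site comparison view of slow (µs-ms) exchange, solvent exposure and
fast (ns-µs) fluctuation.  Writes results/site_flexibility_{a,b}.tsv.
"""

from pathlib import Path

import pandas as pd

OUT = Path("results")

for name in ("a", "b"):
    parts = []
    fits = pd.read_csv(OUT / f"dispersion_fits_{name}.tsv", sep="\t")
    parts.append(fits.set_index("residue_id")[["delta_rex", "class"]])
    hdx = pd.read_csv(OUT / "hdx_fits.tsv", sep="\t")
    hdx = hdx[hdx["isoform"] == name]
    parts.append(hdx.set_index("residue_id")[["k_hd", "censored"]])
    b = pd.read_csv(OUT / f"bfactors_{name}.tsv", sep="\t")
    parts.append(b.set_index("residue_id"))
    table = pd.concat(parts, axis=1)
    table.index.name = "residue_id"
    table.to_csv(OUT / f"site_flexibility_{name}.tsv", sep="\t",
                 float_format="%.6g")
    covered = table.notna().sum()
    print(f"isoform {name.upper()}: site table with "
          f"{len(table)} residues ({covered['delta_rex']} CPMG, "
          f"{covered['k_hd']} HDX, {covered['b_factor']} B-factor)")
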