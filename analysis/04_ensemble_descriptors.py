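#!/usr/bin/env python
"""Structural-descriptor comparison of the two synthetic ensembles.

Computes the ensemble summary (mean SASA, hydrogen-bond count, average
Cα B-factor, radius of gyration, secondary-structure content) for both
isoform ensembles, plus the occupancy of the constructed tight-turn
hydrogen bond (donor 6 NH → acceptor 2 CO, the analogue of a partially
broken turn contact).  The flexible ensemble (B) shows the expected
ordering: higher average B-factor and SASA, fewer hydrogen bonds, lower
bond occupancy.

Reads results/data/, writes results/ensemble_summary.json and per-residue
B-factor tables.
"""

import json
from pathlib import Path

import pandas as pd

from flexprofiler import io as fio
from flexprofiler.ensemble_descriptors import bfactors, hbond_occupancy, \
    summarize

DATA = Path("results/data")
OUT = Path("results")

summaries = {}
for name in ("a", "b"):
    ens = fio.read_ensemble_pdb(DATA / f"ensemble_{name}.pdb")
    s = summarize(ens, sasa_points=240)  # coarser lattice: 200-model means
    b = bfactors(ens)
    pd.DataFrame(sorted(b.items()), columns=["residue_id", "b_factor"]
                 ).to_csv(OUT / f"bfactors_{name}.tsv", sep="\t",
                          index=False, float_format="%.6g")
    occ = hbond_occupancy(ens, (6, "N"), (2, "O"))
    summaries[name] = {"sasa": s.sasa, "n_hb": s.n_hb, "avg_b": s.avg_b,
                       "rg": s.rg, "ss_fractions": s.ss_fractions,
                       "turn_bond_occupancy": occ}
    print(f"isoform {name.upper()}: SASA {s.sasa:.0f} A^2, "
          f"nHB {s.n_hb:.1f}, avg B {s.avg_b:.1f} A^2, Rg {s.rg:.2f} A, "
          f"turn bond occupancy {occ:.2f}")

with open(OUT / "ensemble_summary.json", "w") as fh:
    json.dump(summaries, fh, indent=2)
a, b = summaries["a"], summaries["b"]
print("flexible isoform B has higher avg B, fewer H-bonds, lower turn-bond "
      "occupancy:",
      b["avg_b"] > a["avg_b"] and b["n_hb"] < a["n_hb"]
      and b["turn_bond_occupancy"] < a["turn_bond_occupancy"])
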