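#!/usr/bin/env python
"""Site variability and leave-one-site-out replication of the group effect.

Maps the joint site F test and reruns the whole group analysis once per
held-out site, counting per-vertex replications of corrected-significant,
sign-consistent clusters.  Writes results/losov_counts.npy and
results/losov_summary.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from surfhomog import adjust_reho, build_icosphere, losov, site_effect_map

OUT = Path(__file__).resolve().parents[1] / "results"
mesh = build_icosphere(3)
maps = np.load(OUT / "reho_stack.npy")
jac = np.load(OUT / "jacobian_stack.npy")
pheno = pd.read_csv(OUT / "phenotypes_retained.csv")
truth = json.loads((OUT / "ground_truth.json").read_text())

yadj = adjust_reho(maps, pheno, jac)
site_fit = site_effect_map(yadj, pheno)
np.save(OUT / "site_f_map.npy", site_fit.stat["site"])
frac = (site_fit.p["site"] < 0.05).mean()
print(f"site F test: {frac:.1%} of vertices at p < 0.05 "
      f"(site offsets were simulated at ±0.02 ReHo)")

res = losov(maps, pheno, jac, mesh, n_permutations=300, seed=2026)
np.save(OUT / "losov_counts.npy", res.replication_count)

region = np.array(truth["effect_region"])
rows = [{"held_out_site": site, "n_significant_vertices": int(mask.sum())}
        for site, mask in res.fold_masks.items()]
pd.DataFrame(rows).to_csv(OUT / "losov_summary.csv", index=False)

print(f"LOSOV over {res.n_sites} sites: max replication count "
      f"{res.replication_count.max()} (bound {res.n_sites})")
print(f"seeded-region replication counts: "
      f"median {np.median(res.replication_count[region]):.0f}, "
      f"max {res.replication_count[region].max()}")
print(f"wrote {OUT / 'losov_counts.npy'} and {OUT / 'losov_summary.csv'}")
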