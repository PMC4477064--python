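#!/usr/bin/env python
"""Nuisance-adjusted group GLM with permutation cluster inference.

Stage 1 removes global-mean ReHo, meanFD, mcBBR and the vertexwise Jacobian
across subjects; stage 2 fits diagnosis + site + age + fIQ + diagnosis×age
per vertex.  Clusters of |p| < 0.01 vertices are corrected at α = 0.05 by
within-site label permutation, and recovery of the seeded ground truth is
scored with the Dice coefficient.  Writes results/clusters.csv and the
signed log10(p) maps.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from surfhomog import adjust_reho, build_icosphere, cluster_correct, \
    find_clusters, fit_group_glm

OUT = Path(__file__).resolve().parents[1] / "results"
mesh = build_icosphere(3)
maps = np.load(OUT / "reho_stack.npy")
jac = np.load(OUT / "jacobian_stack.npy")
pheno = pd.read_csv(OUT / "phenotypes_retained.csv")
truth = json.loads((OUT / "ground_truth.json").read_text())

yadj = adjust_reho(maps, pheno, jac)
np.save(OUT / "yadj_stack.npy", yadj)
fit = fit_group_glm(yadj, pheno)
for term in ("group", "group_x_age", "site"):
    np.save(OUT / f"slp_{term}.npy", fit.signed_log_p_maps[term])

rows = []
recovered = {}
for term in ("group", "group_x_age"):
    clusters = find_clusters(fit.signed_log_p_maps[term], mesh, 0.01)
    res = cluster_correct(clusters, yadj, pheno, mesh, term=term,
                          n_permutations=500, seed=2026)
    sig = res.significant_clusters()
    recovered[term] = sorted({int(v) for c in sig if c.sign > 0 for v in c.vertices})
    print(f"{term}: {len(clusters)} raw clusters, {len(sig)} significant")
    for i, c in enumerate(res.clusters):
        rows.append({"term": term, "cluster": i, "vertex_count": c.vertex_count,
                     "sign": c.sign, "peak_vertex": c.peak_vertex,
                     "peak_signed_log_p": round(c.peak_signed_log_p, 3),
                     "corrected_p": c.corrected_p})

pd.DataFrame(rows).to_csv(OUT / "clusters.csv", index=False)

true_region = set(truth["effect_region"])
rec = set(recovered["group"])
dice = 2 * len(rec & true_region) / (len(rec) + len(true_region)) if rec else 0.0
print(f"group-effect recovery: Dice {dice:.3f} vs the seeded region "
      f"({len(true_region)} vertices)")

iregion = np.array(truth["interaction_region"])
print(f"interaction t in seeded region: mean {fit.stat['group_x_age'][iregion].mean():.2f} "
      "(positive = patients steeper with age)")
print(f"wrote {OUT / 'clusters.csv'}")
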