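#!/usr/bin/env python
"""Spatial and temporal organization of hubs and cliques in a droplet with
planted microstructure.

Finding: the chains identified as betweenness hubs sit interior to the
chains identified as clique members (median radius well inside the planted
cluster shell), and clique roles persist across frames while hub identity
turns over — the hub-inner/clique-outer and clique-lifetime > hub-lifetime
orderings.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from condnet.forcefield import load_parameter_table
from condnet.network import (betweenness, build_interaction_graph,
                             identify_cliques, identify_hubs)
from condnet.profiles import build_role_timeline, dense_phase_com, role_lifetimes
from condnet.sequences import ResidueSequence
from condnet.synthetic import generate_planted_droplet
from condnet.trajio import all_chain_coms

OUT = Path("results")
OUT.mkdir(exist_ok=True)

model = load_parameter_table()
seq = ResidueSequence("Y12", "Y" * 12)
pd_drop = generate_planted_droplet(seq, model, seed=21, n_frames=13)
traj = pd_drop.trajectory
masses = model.masses_for(traj[0])

hubs_pf, cliques_pf, rows = [], [], []
for k, frame in enumerate(traj.frames):
    ig = build_interaction_graph(frame, model, 300.0, 5.0)
    cb = betweenness(ig)
    hubs = identify_hubs(ig, cb, n_hubs=4)
    cliques = identify_cliques(ig, n_cliques=3, max_shared=2)
    hubs_pf.append(hubs)
    cliques_pf.append(cliques)
    com = dense_phase_com(frame, masses)
    coms = all_chain_coms(frame, masses)
    for c in hubs.hubs:
        rows.append({"frame": k, "chain": c, "role": "hub",
                     "r": float(np.linalg.norm(coms[c] - com))})
    for grp in cliques.cliques:
        for c in grp:
            rows.append({"frame": k, "chain": c, "role": "clique",
                         "r": float(np.linalg.norm(coms[c] - com))})

df = pd.DataFrame(rows)
df.to_csv(OUT / "microstructure_roles.tsv", sep="\t", index=False)
med = df.groupby("role")["r"].median()
print(f"median radial distance: hubs {med['hub']:.1f} Å, cliques {med['clique']:.1f} Å "
      f"(planted cluster shell at {pd_drop.radius:.1f} Å)")

lt = role_lifetimes(build_role_timeline(hubs_pf, cliques_pf, traj[0].chain_labels))
lt_df = pd.DataFrame({"chain": lt["chain_ids"], "hub_fraction": lt["hub_fraction"],
                      "clique_fraction": lt["clique_fraction"]})
lt_df.to_csv(OUT / "role_lifetimes.tsv", sep="\t", index=False)
cluster = set(pd_drop.clique_chain_ids)
cf = lt_df[lt_df.chain.isin(cluster)].clique_fraction
print(f"clique-member lifetime fraction: min {cf.min():.2f} (planted chains)")
print(f"hub lifetime fraction: max {lt_df.hub_fraction.max():.2f} (core turns over)")
print(f"wrote {OUT / 'microstructure_roles.tsv'} and {OUT / 'role_lifetimes.tsv'}")
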