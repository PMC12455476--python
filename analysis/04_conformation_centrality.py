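#!/usr/bin/env python
"""Single-chain conformation versus network centrality, plus the
ideal-chain shape-anisotropy reference.

Finding: freely jointed 150-bond chains average kappa^2 ~ 0.39; on a
desk-scale droplet the per-chain log10(Rg)-log10(C_B) relation is summarized
by a least-squares power-law fit written to the manifest table.
"""

from pathlib import Path

import pandas as pd

from condnet.conformation import ideal_chain_kappa2, loglog_power_fit
from condnet.pipeline import RunConfig, run_pipeline

OUT = Path("results")
OUT.mkdir(exist_ok=True)

kappa2 = ideal_chain_kappa2(150, n_samples=10_000, seed=1)
print(f"ideal-chain kappa^2 (150 bonds, 1e4 samples): {kappa2:.3f}")

# a looser 2 k_B T threshold keeps the desk-scale static droplet's graph
# dense enough for per-chain centralities
manifest = run_pipeline(RunConfig(
    out_dir=str(OUT / "droplet_run"), sequence="(YS)75", n_chains=20,
    droplet_radius=40.0, box=170.0, seed=11, langevin_steps=0,
    threshold_multiple=2.0))
df = pd.read_csv(manifest["outputs"]["chain_metrics"], sep="\t")
row = {"kappa2_ideal_150": kappa2}
try:
    fit = loglog_power_fit(df["C_B"].to_numpy(), df["Rg"].to_numpy())
    print(f"Rg vs C_B power law on {fit.n_points} chains: slope {fit.slope:+.3f}, "
          f"R^2 = {fit.r_squared:.2f}")
    row.update(rg_cb_slope=fit.slope, rg_cb_intercept=fit.intercept,
               rg_cb_r2=fit.r_squared)
except ValueError as exc:
    print(f"Rg vs C_B fit unavailable on this droplet: {exc}")
pd.DataFrame([row]).to_csv(OUT / "conformation_summary.tsv", sep="\t", index=False)
print(f"wrote {OUT / 'conformation_summary.tsv'} (chain table under {OUT/'droplet_run'})")
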