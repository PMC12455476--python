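# condnet

Analysis of the *microstructure* of biomolecular condensates: the transient
network of intermolecular crosslinks inside a dense phase formed by
sticker–spacer polymers, such as the low-complexity domains (LCDs) of
phase-separating RNA-binding proteins (hnRNPA1, FUS, EWSR1, TIA1) and binary
tyrosine/serine ("YS") model sequences.

The package is written for people studying coarse-grained condensate
simulations who want to go from bead-resolution configurations to
graph-theoretic and material-property observables without cluster-scale MD:
it ships a desk-scale synthetic-data module (droplet/slab builders, planted
microstructure, a Langevin mini-integrator) in place of production runs.

## What it computes

**Interaction graphs.** For each frame, chains a and b are connected by an
unweighted, undirected edge when their inter-chain energy under a
Mpipi-style potential (harmonic bonds; Wang–Frenkel short-range contacts;
Debye–Hückel electrostatics with ε_r = 80, κ⁻¹ = 7.95 Å, 35 Å cutoff) falls
below a thermal threshold:

    edge(a, b)  ⇔  E_pair,ab < −m·k_B·T        (default m = 5)

**Small-world statistics.** With C the mean clustering coefficient, L the
mean shortest path length, and C_rand/L_rand, C_latt/L_latt ensemble means
over matched Erdős–Rényi and degree-preserving latticized references:

    σ_sw = (C/C_rand) / (L/L_rand)        ω_sw = L_rand/L − C/C_latt

σ_sw ≈ 1 and ω_sw ≈ 1 for random graphs, ω_sw ≈ −1 for lattices, and
−0.3 ≤ ω_sw ≤ 0.3 marks the small-world band.

**Hubs and cliques.** Hubs are the n_h chains of highest normalized
betweenness centrality C_B (default 10); cliques are the largest maximal
cliques, reported greedily while sharing fewer than three members with any
previously reported clique. Their radial distributions (normalized by the
dilute-side interfacial bound from a logistic fit of the radial density
profile) and per-chain role lifetimes quantify the spatial and temporal
organization of the microstructure.

**Single-chain and material properties.** Gyration tensor, R_g, relative
shape anisotropy κ² = 1 − 3(λ₁λ₂+λ₂λ₃+λ₃λ₁)/(λ₁+λ₂+λ₃)², power-law fits of
per-chain metrics against C_B, instantaneous COM displacements, surface
tension by the mechanical (Kirkwood–Buff) and stress-profile routes,
coexistence densities with the law of coexisting densities + rectilinear
diameters (T_c, ρ_c), excluded volume, overlap concentration c*, and the
effective packing density φ_rel = ρ_n/c*.

**Sequence metrics.** Sticker fraction f_h and blockiness
f_B = 1 − B_act/B_max with B_max = min(2·min(n_Y, n_S), n−1), so the
alternating sequence gives f_B = 0 and a diblock f_B → 1.

## Worked example

The packaged sequence fixtures (four LCDs; eleven YS variants of length
150, one of them the fixed scrambled variant):

```sh
$ condnet sequences
name    n    f_h     f_B
A1-LCD      137  0.1387
FUS-LCD     163  0.1472
EWSR1-LCD   280  0.1393
TIA1-LCD    97   0.1546
(S9Y)15     150  0.1     0.0333
(S4Y)30     150  0.2     0.0167
(SSY)50     150  0.3333  0.01
(YS)75      150  0.5     0.0
(YYS)50     150  0.6667  0.01
Y150        150  1.0     1.0
S150        150  0.0     1.0
(S12Y3)10   150  0.2     0.6833
(S24Y6)5    150  0.2     0.85
S120Y30     150  0.2     0.9833
(S120Y30)scr 150 0.2     0.2333
```

All four LCDs sit near the aromatic sticker fraction f_h ≈ 0.14; the YS
variants sweep f_h from 0 to 1 at fixed length, and at fixed f_h = 0.20
sweep blockiness from 0.017 (evenly spaced stickers) to 0.983 (diblock).

Estimator validation (`python analysis/02_smallworld_validation.py`):

```
             ER: sigma =  0.985  omega =  0.995
   ring_lattice: sigma =  5.058  omega = -0.969
 watts_strogatz: sigma = 38.444  omega = -0.018
```

i.e. the estimators place random graphs at (σ, ω) ≈ (1, 1), lattices at
ω ≈ −1, and Watts–Strogatz graphs inside the small-world band — the three
corners they must resolve before being applied to condensate graphs.

Microstructure recovery on a droplet with planted organization
(`python analysis/03_droplet_microstructure.py`):

```
median radial distance: hubs 7.4 Å, cliques 43.9 Å (planted cluster shell at 42.0 Å)
clique-member lifetime fraction: min 0.92 (planted chains)
hub lifetime fraction: max 0.31 (core turns over)
```

Identified betweenness hubs sit at the droplet center while identified
clique chains sit at the interface, and clique roles persist far longer
than hub roles — the hub-inner/clique-outer and clique-lifetime > hub-lifetime
orderings.

The numbered scripts under `analysis/` run the full sequence→graph→profile→
conformation→thermo chain at desk scale and write their tables under
`results/`. `condnet run --config cfg.yaml --seed 1 --out out/` drives the
same pipeline from a YAML config.

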