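# Methods

This note documents the models, conventions, and design choices behind
condnet, in the spirit of a simulation package's model documentation. Units
throughout: Å, kcal/mol, amu, fs for dynamics, ns for trajectory
timestamps; k_B = 1.9872041×10⁻³ kcal mol⁻¹ K⁻¹.

## Energy model

The potential is a residue-resolution sticker–spacer model of the Mpipi
family: one bead per residue, implicit solvent, and

E = E_bond + E_elec + E_pair

* **Bonds.** Harmonic, E = k(r − r₀)² with k = 19.2 kcal mol⁻¹ Å⁻² and
  r₀ = 3.81 Å. We use the engine convention *without* the ½ factor, which
  matches the stated unit of k; a ½-factor reading would halve bond
  energies.
* **Short-range contacts.** Generalized Wang–Frenkel potential with ν = 1,
  per-pair (ε, σ, μ), cutoff R_c = 3σ, and the normalization prefactor
  α(R_c/σ, μ, ν) chosen so the well depth is exactly −ε. The depth identity
  is asserted numerically for all 210 pairs in the test suite.
* **Electrostatics.** Debye–Hückel screened Coulomb,
  E = C q_i q_j e^{−r/λ_D}/(ε_r r), with ε_r = 80, λ_D = 7.95 Å, truncated
  at 35 Å. The truncation discontinuity of the screened tail is below
  5×10⁻³ kcal/mol per unit charge product.

**Parameter table.** The packaged TSV (`condnet/data/mpipi_params.tsv`) is
a *synthetic, model-faithful reconstruction*: the published model's full
per-pair table is distributed externally and is not printed in any source
this package embeds. The table uses standard residue masses, HPS-style bead
diameters, fractional side-chain charges (±0.75 e; His +0.375 e), and
per-residue Wang–Frenkel energy scales with geometric-mean combining,
anchored so that the Y–Y well depth is exactly 0.42 kcal/mol — the one
per-pair value the model family pins down publicly. Every loader accepts a
user TSV in the same layout (`pair A B eps [sigma [mu]]` lines override
individual pairs), so a full published table can be swapped in without code
changes. Quantities that depend on the detailed off-anchor values (absolute
chain-pair energies of mixed sequences) should be interpreted accordingly;
the graph-level analyses are threshold-based and robust to the overall
scale through the m·k_BT criterion.

1–2 bonded bead pairs are excluded from the nonbonded terms.

**Stresses.** Per-bead virial stresses are stored in pressure·volume units
(kcal/mol): each pair/bond contribution r⊗f is split equally between the
two partners, and the kinetic term m v⊗v is added when velocities are
present. Summing per-bead tensors and dividing by the box volume reproduces
the global virial pressure tensor (asserted against an independent
double-loop oracle).

## Interaction graphs and small-world estimators

Edges connect chains with inter-chain energy below −m·k_BT (default m = 5;
the multiple tunes how long-lived the recorded associations are). Energies
are accumulated with a periodic KD-tree neighbor list; equality with the
brute-force double loop is asserted in tests.

σ_sw and ω_sw compare C (mean local clustering, full graph) and L (mean
shortest path length, computed on the largest connected component, with
the component fraction reported) against reference ensembles, by default
n_ref = 10 of each:

* **Random references**: Erdős–Rényi graphs with matched node and edge
  counts (G(n, m)).
* **Lattice references**: a direct *banded* degree-preserving
  latticization — edges are packed greedily onto the smallest ring offsets
  compatible with the degree sequence. Swap-based latticization converges
  far too slowly at n ≈ 2000 (C_latt ≈ 0.02 after five sweeps versus
  ≈ 0.64 for the banded construction on an 8-regular-like graph), which
  would corrupt ω_sw; the banded construction approximates the ideal
  lattice the estimators are defined against. Parity can strand one or two
  stub pairs; the edge count then differs by a few edges at most.

C and L are evaluated through igraph (identical values to networkx,
roughly an order of magnitude faster; equivalence is asserted on small
graphs). networkx remains the graph container and supplies betweenness
centrality, maximal-clique enumeration (Bron–Kerbosch), and the graph
generators.

**Hubs** are the n_h = 10 nodes of highest normalized betweenness
(normalization 1/C(N−1, 2)); ties break by ascending chain id. **Cliques**
are maximal cliques scanned in order of decreasing size (lexicographic
tie-break) and accepted greedily while sharing ≤ 2 members with every
previously accepted clique, up to n_c = 10.

σ_sw on sparse ER graphs carries ~10% per-graph noise from triangle-count
statistics (mean triangle count ≈ ⟨k⟩³/6 ≈ 85 at n = 2000, ⟨k⟩ = 8), so
σ-based checks average several graph seeds; ω_sw is far tighter (sd ~10⁻³).

## Spatial and temporal organization

Radial mass-density profiles are binned about the dense-phase center of
mass (the plain mass-weighted bead center — the droplets analysed here keep
the dense phase compact and interior) in 5 Å shells, in g/cm³. The
interface is a logistic fit ρ(r) = ρ_dil + (ρ_dense − ρ_dil)/(1 + e^{(r−r₀)/w})
with bounded parameters; the interfacial bounds r₉₅/r₀₅ are where the
fitted curve crosses 95% and 5% of the dense-phase plateau value. Fit
failure (no plateau ≥ 2× the dilute level, non-convergence, inverted
bounds) raises explicitly — no silent defaults. A tanh sigmoid is an
algebraic reparameterization of the same curve; the logistic form is the
one implemented.

Hub/clique radial distributions are normalized by r₀₅ (the dilute-side
bound) and reported as unit-area histograms. Role lifetimes are per-chain
fractions of flagged frames over a contiguous window (production analyses
use 20% of the trajectory). Instantaneous displacement at frame t is the
mean of the two leg lengths ‖r(t)−r(t−δ)‖ and ‖r(t+δ)−r(t)‖ (the
alternative half-end-to-end reading would underestimate direction-reversing
motion); the normalized value divides by the contour length (n−1)·3.81 Å as
the natural reading of a fully extended linear conformation.

## Conformation

Gyration tensors are mass-weighted by default (equal-weight mode available
for comparison with polymer-theory closed forms), eigenvalues sorted
descending, R_g = √(λ₁+λ₂+λ₃), κ² as above (0 isotropic, 1 collinear).
Chains are unwrapped by nearest-image chaining along the backbone before
analysis. The freely-jointed-chain reference κ² is Monte-Carlo estimated;
at 150 bonds the converged mean is 0.393 (≈ 0.39 at two decimals) with an
SE of ~0.002 at 10⁴ samples. Power-law fits are least-squares lines in
log₁₀–log₁₀ space on per-chain points pooled over sampled frames;
zero-centrality chains are excluded before the log transform (the log is
undefined there).

## Thermodynamics

Surface tension: the mechanical route γ = (L_z/2)(⟨P_zz⟩ − ½(⟨P_xx⟩+⟨P_yy⟩))
from box-averaged pressure tensors, and the stress-profile route
integrating σ_N(z) − σ_T(z) over two equal windows centred on the
interfaces and averaging the two interfaces. The window thickness defaults
to the fitted 95%–5% span. The routes agree exactly when the anisotropy is
confined to the windows; tests assert 2% agreement on synthetic slabs. Unit
conversion (kcal mol⁻¹ Å⁻² → mN/m, factor 694.77) lives in one audited
constant.

Coexistence fitting solves jointly ρ_d − ρ_l = A(1 − T/T_c)^β and
(ρ_d + ρ_l)/2 = ρ_c + s(T_c − T) by least squares, with β = 0.325 (3-D
Ising) as a configurable parameter. The fit is exact on clean synthetic
data and recovers T_c within 2% under 1% multiplicative noise; a fitted
T_c at or below the largest input temperature is reported as failure.

Excluded volume sums bead sphere volumes (radius σ_i/2 from the parameter
table) minus the sphere–sphere lens intersection of every bonded pair at
its sampled separation, clamped to the smaller sphere when engulfed;
validated against Monte-Carlo union-volume integration to 0.5%. The
overlap concentration is c* = N/V_ex and the packing density
φ_rel = ρ_n/c*, with ρ_n the bead count inside a sphere of the fitted
interface radius centred on the dense-phase COM (beads, not mass-weighted).

## Synthetic data

The generators emulate the *inputs* of the production analyses, not their
thermodynamics:

* **Droplets/slabs**: self-avoiding random walks with bond length 3.81 Å;
  placements closer than 0.8× the mean bead diameter to any existing bead
  are rejected (cheap, sufficient for analysis fixtures). Dense-phase chain
  centers are uniform in the sphere (or slab), with dilute chains outside.
  Desk-scale defaults are ~30 chains × 50 beads; production-scale counts
  remain a config choice.
* **Planted microstructure**: chains are straight rods aligned along z on a
  star-with-triangles layout — a connective core at the center, radial
  bridge chains at a fixed contact spacing, and fully connected triangles
  at the periphery. Rod geometry makes every planted contact strongly
  bound (−8…−13 kcal/mol at the default spacing versus the −2.95 kcal/mol
  edge threshold) and every non-contact exactly disconnected, which
  SAW-grown blobs cannot guarantee. Across frames the triangles keep their
  slots while core chains permute, so planted cliques persist and hub
  identity turns over. This is a geometric idealization for pipeline
  validation: passing it demonstrates recovery of planted organization,
  not that equilibrium droplets organize this way.
* **Langevin mini-integrator**: BAOAB splitting, default friction
  0.01 fs⁻¹ (a stand-in choice; the emulated production engine thermostats
  differently), dt ≤ 10 fs guarded by the stiff bond term. It satisfies
  equipartition within 5% and is used for relaxation and single-chain
  sampling, not for claims about phase behavior, T_c, or surface-tension
  values at production scale.
* **Reference graphs**: seeded ER / ring-lattice / Watts–Strogatz
  generators for estimator validation.
* **Synthetic stress fields**: Gaussian interfacial anisotropy profiles
  with known integrals, for cross-validating the two surface-tension
  routes.

What passing tests on these fixtures does *not* show: agreement with
wet-lab data, converged equilibrium ensembles, or production-scale values
of T_c and surface tension.

## Numerical choices and degenerate inputs

* Blockiness uses B_max = min(2·min(n_Y, n_S), n−1), the junction-count
  maximum at fixed composition; homopolymers are degenerate (f_B ≡ 1,
  flagged). Sequences outside {Y, S} are rejected.
* Dump I/O: positions are stored unwrapped; wrapped input is unwrapped via
  image flags when present, else backbone nearest-image chaining. A bond
  longer than half the box after unwrapping raises (broken topology).
  Scaled and unscaled dump dialects are both read; files written by this
  package carry an `element` column so round trips need no side files.
* Interface crossings below the dilute baseline, overlapping stress
  windows, spheres beyond the half-box, T_c below the data range, empty
  sticker sets, all raise explicit errors rather than returning defaults.
* Degenerate shapes: coincident beads give R_g = 0 (valid); κ² of an
  all-zero tensor raises.

## Known limitations

The packaged pair-parameter table is representative rather than published
values (swappable, see above). The Langevin integrator is not a validated
thermodynamic sampler. Triclinic boxes, binary dump dialects, weighted or
directed graph variants, percolation analysis, MSD/diffusion estimation,
and Ewald electrostatics are out of scope.
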