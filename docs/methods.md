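# Methods

## Model

The package implements a structure-based statistical-mechanical treatment
of allostery on top of a Cα elastic network. A protein structure is reduced
to one bead per residue at the Cα position (PDB `ATOM` records only; the
first MODEL; first-listed altLoc; residues without a Cα are skipped with a
warning; HETATM ligands are not part of the network). Beads closer than a
cutoff R<sub>c</sub> are joined by Hookean springs of uniform stiffness k,
giving the standard anisotropic-network Hessian: each edge (i,j)
contributes the 3×3 block −k·d d<sup>T</sup>/|d|² off-diagonal (d the
equilibrium inter-Cα vector) and its negative to both diagonal blocks.
Uniform translations are exact null vectors of this matrix by construction;
a connected, non-degenerate 3-D structure has exactly six zero-frequency
rigid-body modes.

Two ensembles are compared: the unperturbed network (0) and a perturbed
network (P) obtained by editing spring constants —

- binding: all pairwise springs among site members set to
  α<sub>bind</sub>·k (created if absent, up to a pair cutoff), modelling the
  rigidifying effect of a bound ligand;
- UP / DOWN mutation of residue m: every existing spring incident to m
  multiplied by α<sub>up</sub> > 1 / α<sub>down</sub> < 1. Mutations never
  create or remove contacts; composite perturbations multiply factors on
  shared edges.

For each state the allosteric-potential parameters
ε<sub>μ,i</sub> = Σ<sub>j∈N(i)</sub> |e<sub>μ,i</sub> − e<sub>μ,j</sub>|²
are computed over the non-rigid modes, with the neighbor set N(i) taken
from the contact topology. Treating the mode amplitudes as independent
zero-mean Gaussians with variance 1/ε<sub>μ,i</sub> and integrating them
out, the free-energy difference per residue is
Δg<sub>i</sub> = ½ k<sub>B</sub>T Σ<sub>μ</sub> ln(ε<sup>(P)</sup><sub>μ,i</sub>/ε<sup>(0)</sup><sub>μ,i</sub>).
The modulation Δh subtracts the per-chain mean of Δg, so ⟨Δh⟩ = 0 per chain
identically; site modulation is the arithmetic mean of Δh over a site, and
the modulation range is Δh(UP) − Δh(DOWN) at a position. Signaling maps
apply this per-position over the whole sequence: the unperturbed modes and
ε<sup>(0)</sup> are computed once, then one Hessian eigendecomposition per
scanned position.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 11.0 Å | Cα contact cutoff of the network. 10–13 Å is the usual Cα-ENM window; 11 Å keeps helical i→i+3/i+4 and cross-interface contacts without saturating the graph. |
| `base_k` | 1.0 | spring constant (arbitrary energy/Å² units). Δg depends only on eigenvectors, so the overall stiffness scale provably cancels. |
| `alpha_binding` | 10 | binding springs are "strong interactions": an order of magnitude above background. |
| `alpha_up`, `alpha_down` | 2, 0.1 | moderate stiffening for a bulky substitution; near-removal of contacts for an Ala/Gly-like one. The magnitudes scale Δh but not the structure of the response. |
| `binding_pair_cutoff` | 15 Å | maximum span of a binding-induced spring; site members farther apart are not coupled directly. |
| `temperature_k` | 300 K | only used to express k<sub>B</sub>T-valued profiles in kcal/mol (k<sub>B</sub>T ≈ 0.596 kcal/mol). |
| `epsilon_floor` | 1e-12 | relative floor under which a mode term is skipped in the Δg sum (see below). |
| `rigid_tolerance` | 1e-9 | relative eigenvalue threshold flagging rigid-body modes. |
| `mode_count` | all | number of lowest non-rigid modes retained; exposed because mode truncation is a common ENM practice, but the default uses the full spectrum. |
| `scope` | chain | baseline for Δh: per-chain mean (default) or global mean. |
| `topology` | unperturbed | neighbor set for ε in the perturbed state; the default compares like with like, binding-added springs entering only through the modes. |

## Numerical choices

- **Mode pairing.** The Δg sum pairs modes of the two ensembles by
  ascending-eigenvalue rank over the non-rigid spectrum (equal counts are
  enforced). Rank pairing is the only generic well-defined choice when the
  perturbation reorders the spectrum.
- **ε floor.** In locally rigid neighborhoods ε can underflow; mode terms
  where either state's ε falls below 1e-12 × that residue's maximum ε are
  skipped symmetrically and counted in the result's diagnostics, avoiding
  log-of-zero without biasing one state.
- **Rigid modes.** Modes with λ ≤ 1e-9·λ<sub>max</sub> are rigid. More than
  six rigid modes means a disconnected network or degenerate geometry
  (perfectly collinear inputs, under-constrained linkers); this raises an
  error that lists the connected components, rather than silently producing
  meaningless ratios. The two-bead system (five rigid + one stretch mode)
  is the allowed special case.
- **Degenerate eigenvalues.** Within a degenerate subspace eigenvectors are
  solver-dependent, so Δg of individual modes is not basis-invariant there.
  Analytic tests use fixtures with simple spectra (seeded jitter breaks the
  accidental degeneracies of ideal shapes); symmetry tests compare only
  permutation-related whole profiles, which are basis-invariant.
- **Determinism.** All computations are deterministic given the inputs;
  scan rows are independent and computed sequentially, so any future
  parallel evaluation must reproduce the sequential result bit-for-bit.

## Synthetic structures

The fixture generator emulates only the geometric/topological features the
model consumes: chain connectivity at ~3.8 Å Cα spacing, helical geometry
(rise 1.5 Å, 100° twist, radius 2.3 Å), compact lattice domains, a
two-domain dumbbell with a narrow triangulated linker (a single-strand
linker is floppy in a central-force network and is deliberately avoided),
and a homodimer with exact two-fold symmetry for permutation tests.
Jitter is drawn from a seeded uniform cube (default 0; ~0.1–0.4 Å where a
simple spectrum or generic rigidity is needed). These fixtures contain no
side chains, no realistic packing density gradients, and no
sequence-specific interactions, so passing tests demonstrate the
correctness and the provable invariances of the method — not predictive
accuracy on real proteins, which depends on structure quality and on the
generic α parameters.

Problem sizes in the shipped tests and the acceptance script (30-residue
helices, 20–24-residue dimers/dumbbells, a 100-residue scan) were chosen as
the smallest systems that exercise every property non-trivially; the
method itself runs comfortably to N ≈ 1000 with dense eigensolvers.

## Design decisions

- The Cα harmonic potential is realized as the standard distance-cutoff
  anisotropic network model with uniform springs. The free-energy equations
  consume only mode shapes, so any consistent harmonic network exercises
  the full method; the cutoff and stiffness are configurable.
- ε sums |e<sub>μ,i</sub> − e<sub>μ,j</sub>|² over contact neighbors
  unweighted by k<sub>ij</sub>, as the formula is stated; weighting by
  spring constants would couple ε to the stiffness scale and break the
  provable uniform-scaling invariance.
- Binding creates springs among site members even beyond the network
  cutoff (bounded by `binding_pair_cutoff`): a bound ligand couples
  residues that do not touch each other directly.
- Chain breaks: residues are connected only by the distance cutoff; no
  pseudo-bonds are added across gaps in author numbering.
- Site membership is always an explicit input (labels + residue lists,
  optionally grouped by symmetry); the package does not guess sites from
  ligand proximity.

## Limitations

- Free energies are in k<sub>B</sub>T of a generic harmonic model; they
  rank residues and sites and expose symmetry/cooperativity patterns, but
  absolute magnitudes depend on the α parameters and cutoff and should not
  be read as calorimetric values.
- Mutations are generic stiffen/soften operations; there is no
  amino-acid-specific force field.
- Collinear or mechanically under-constrained inputs are rejected rather
  than regularized.
- Dense eigendecomposition bounds practical size to a few thousand
  residues.
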