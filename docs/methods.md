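# Methods

This note records the models the toolkit implements, the conventions and
defaults it adopts, and the choices made where more than one reasonable
design existed. Units are Angstrom for lengths, kelvin for temperature,
kJ/mol for energies and elementary charges for charge, throughout.

## Dendrimer topology model

Peptide dendrimers are modeled at residue (bead) resolution as a rooted
tree. Sequences are written as repeat blocks listed periphery-to-core
(`(KL)_8(*K*KL)_4(*K*LL)_2*K*LLLL`); uppercase letters are L-amino acids,
lowercase D; `*K*` (configurable sentinel) marks a branching lysine whose
side-chain amine is amidated to carry a second arm; `(C_16)` marks a
palmitoylated lysine. Because these molecules are synthesized C-to-N, the
tree is rooted at the molecule's C-terminus: every branching lysine then
has exactly two children (the alpha-amino arm first, the side-chain arm
second — the canonical child order used for serialization and permutation
indexing), linear residues have at most one child, and the leaves are the
peripheral N-termini. Repeat counts must halve toward the core (8, 4, 2,
then an unrepeated core block); anything else is a parse error naming the
offending block. The two palmitoylated core lysines of the lipidated
variant are stored as a linear acylated chain below the lowest branch
node; their connectivity never enters any analysis because acylated
residues carry no titratable site and sit below every swappable node.

Titratable sites are free lysine side-chain amines (linear, non-acylated
lysines) and the peripheral N-termini; branching lysines titrate at
neither amine and C-termini are amide-capped. Both site kinds are cationic
when protonated. For the full third-generation dendrimer this gives
4 + 8 + 8 = 20 sites; the G2 Lys→Leu mutant has 16.

**Branch-swap symmetry group.** At every branching lysine whose two child
subtrees are isomorphic (same shape, codes, chirality, roles, acylation)
the arms may be exchanged without changing the molecule. The group is
derived from subtree isomorphism rather than hard-coded, so an asymmetric
node simply contributes no swap (logged, not an error). Compositions of
the independent swaps are enumerated in a fixed node order, which yields
each of the 2^k group elements exactly once (k = 7, hence 128, for a full
G3 dendrimer); the enumeration is closed under composition.

## Structural descriptors

The gyration tensor is mass-unweighted; its principal components are
reported as R_gx ≥ R_gy ≥ R_gz with R_g² their sum of squares. This is
the convention natural to bead-level dendrimer analysis, where
"moments of inertia" are universally quoted on the R_g scale.

* **Asphericity / sphericity.** `A = 1 − 3 R_gz²/R_g²` maps a perfect
  sphere (R_gz² = R_g²/3) to 0 and a collinear arrangement (R_gz = 0)
  to 1; sphericity is `100·(1 − A)` percent. A is a function of R_g and
  the shortest moment only; disks and rods both approach 0% and are
  separated by the shape descriptor.
* **Shape.** With `α = (R_gx + R_gz)/2`, `shape = (R_gy − α)/α` is
  positive when the intermediate moment sits nearer the longest one
  (oblate, disk-like) and negative when nearer the shortest (prolate,
  rod-like). Normalizing by α makes the descriptor dimensionless and
  bounded; the sign convention is the quantity of interest. Degenerate
  triples (R_gx = R_gz) return 0 with a warning.
* **Permutation-corrected RMSD.** For each relabeling in the branch-swap
  group, the mobile frame is permuted, optimally superposed (Kabsch, with
  the proper-rotation determinant correction, batched over all
  relabelings via the closed-form singular-value expression), and the
  minimum RMSD is returned. Superposition is redone per relabeling
  because the optimal fit changes with it. The corrected RMSD is bounded
  above by the naive one and vanishes for pure arm swaps.
* **Central structure.** The representative conformation of a set is the
  one minimizing the row sum of the full symmetric cross-RMSD matrix
  (permutation-corrected by default, switchable); ties break to the
  lowest index.
* **Orientation.** `|z_rest − z_c| − |z_core − z_c|` with z_core the
  geometric center of all generation-0 residues (including core tails —
  a selection override exists) and z_rest the G1+G2+G3 center; positive
  means the hydrophobic core faces the membrane. Including the lipid
  tails in the G0 selection follows the view of the core as the whole
  hydrophobic anchor; the override covers the alternative reading.

## Free-energy landscapes

The 2D probability density over (R_g, RMSD) uses a separable Gaussian
product kernel with per-axis bandwidths (Silverman's d = 2 reference rule,
`h = σ n^{-1/6}`, by default). The grid covers the data range ± 3
bandwidths; the default cell is square with side √0.009 ≈ 0.095 Å — the
grid-parameter value quoted for this analysis family is dimensionally
ambiguous for a 2D surface, so the square-cell reading is a declared
convention and both step sizes are overridable. The density is
renormalized to integrate to one over the grid (trapezoid). The energy
surface is `E = −RT ln(P/P_max)` with R = 8.314×10⁻³ kJ/(mol·K) and
T = 310 K by default, so E = 0 exactly at the density maximum; cells with
P = 0 are +inf in memory and capped (default 50 kJ/mol) when written.

## Titration analytics

Protonation states are binary per (frame, site). Curves are averaged over
frames and the sites of a group — a single site, a (generation, kind)
class (exploiting the pseudo-symmetry that makes same-generation sites
equivalent), or all sites — within each replicate; the curve mean and SEM
are taken **over replicate means**. The replicate, never the frame, is
the unit of independence: CpHMD frames are autocorrelated and the
generators deliberately make no claim about within-run correlation.

The Hill model for cationic groups is
`⟨prot⟩ = 1/(1 + 10^{n (pH − pKa)})`, fitted by unweighted least squares
(no weighting scheme is implied by the data model). A free Hill
coefficient is fitted only when at least three pH points lie inside the
transition region (mean within (0.01, 0.99)); saturated points carry no
slope information and make the free-n problem ill-conditioned, so with
fewer informative points n is pinned at 1 and only the pKa is fitted —
this is exactly the regime of membrane slices where the pKa is an
extrapolation from the two highest pH values. pKa errors are
leave-one-replicate-out jackknife standard errors,
`SE = sqrt((m−1)/m · Σ(θ_i − θ̄)²)`, reported alongside the full-sample
fit. Total charge is the per-frame count of protonated sites (+1 each).

## Membrane profiling

Bilayers are reduced to phosphate reference positions; leaflets are
assigned by the sign of z relative to the membrane center (midpoint of
the leaflet phosphate means) — adequate for non-flip-flopping bilayers.
The interacting leaflet is the one whose mean phosphate plane lies nearer
the dendrimer.

* **Insertion coordinates.** `center` mode: |z − z_center| (structural
  profiles). `insertion` mode: signed distance past the interacting
  leaflet's mean phosphate plane, positive toward the membrane center.
  Both are invariant to global z-translation and lateral periodic wrap.
* **Distances to the dendrimer** for the 6/15/25 Å rules are lateral
  (x/y, minimum-image) distances to the nearest dendrimer bead, matching
  the radial geometry of the thickness profiles; a 3D alternative was
  considered and rejected because it conflates insertion depth with
  lateral proximity (the choice is exposed by the per-function cutoffs).
* **Local deformation.** Mean monolayer thickness (|z_P − z_center|) of
  contact lipids (≤6 Å) minus the same-leaflet bulk reference (>15 Å),
  averaged over frames; SEM over replicates when given. Negative values
  mean contact lipids dragged toward the membrane center. The bulk
  reference is per-leaflet (the interacting one); a whole-bilayer
  reference would mix a perturbed and an unperturbed leaflet.
* **Radial thickness profiles.** Overlapping radial slices of width 1 Å
  stepped by 0.5 Å out to 25 Å; each slice reports mean thickness minus
  bulk. An inward dimple therefore appears as a negative central well,
  protrusion rings as positive deviations — the sign convention of
  deformation-profile figures in this literature.
* **Minimum-sampling rules.** Slices with fewer points than `min_count`
  are discarded (NaN, flagged): defaults 400 for structural observables,
  1500 for protonation, 2500 for pKa slices. "Points" are frames for
  structural observables and (frame × site) observations for protonation
  and pKa, since that is what the slice mean averages; for pKa profiles
  the worst-sampled pH decides. Per-slice pKa values in slices saturated
  at 0 or 1 at every pH are marked undefined rather than erroring.

## Synthetic-data generators

The generators emulate the *statistical structure* of CpHMD output, not
its physics: frames are i.i.d., electrostatics and dynamics are absent,
and nothing about force fields is represented. Passing tests therefore
demonstrates the correctness of the analysis chain on data with known
ground truth — not agreement with any production trajectory.

* **Ensembles.** One bead per residue. Each frame embeds the tree with
  3.8 Å bonds (the Cα–Cα virtual bond) in random directions plus 0.3 Å
  jitter, is rotated to its principal frame, rescaled per axis to the
  target moment ratios and scaled to a per-frame R_g that fluctuates
  (5% relative sd, mean-preserving) about
  `compactness × 3.8 √N` Å. Ensemble-mean R_g and moment ratios converge
  to the targets as 1/√n_frames and are within 2% by n ≈ 500. The
  default `anisotropy_jitter = 0` keeps the ratio targets exact per
  frame; switching it on (~0.05) makes sphericity/shape fluctuate for
  more lifelike descriptor distributions. Unordered anisotropy targets
  are a validation error. pH-dependence studies map pH → compactness
  externally; the generator itself is pH-agnostic (the stored pH is
  metadata).
* **Protonation.** Site/frame states are Bernoulli with the Hill
  probability at the spec's pH; insertion coupling lowers the effective
  pKa by `ΔpKa_max · σ(steepness·(insertion − midpoint))`, a logistic
  desolvation shift with default-free parameters chosen per experiment
  (tests use ΔpKa_max = 3–6, midpoint 0–3 Å, steepness 1 Å⁻¹, spanning
  the several-unit shifts expected from desolvation).
* **Membranes.** Phosphates on a jittered square grid per leaflet at
  ±19 Å (half of the 38 Å phosphate-plane separation of a POPC-like
  bilayer); optional Gaussian dimple `depth·exp(−r²/2w²)` pulls the
  interacting leaflet toward the center around the dendrimer's lateral
  position; z-noise default 0.5 Å. Periodicity is x/y only (slab
  geometry). Note that a Gaussian dimple has infinite support: with a
  15 Å bulk cutoff and a wide dimple, the bulk reference itself is
  slightly displaced, so recovery tests compare against the analytic
  expectation *including* that bulk offset rather than the bare depth.

All generators are bit-reproducible given (spec, seed).

## Problem sizes and verification

The test suite and the acceptance script run the full chain at sizes
chosen to make every statistical assertion sharp at desk scale: ensembles
of 50–600 frames (39-bead dendrimers), titration designs of 10 pH ×
10 replicates × 250 frames × 4 sites (10,000 observations per pH),
membranes of 4096 lipids per leaflet × 15 frames. Statistical assertions
are stated in units of the quantity's own SE (binomial CIs, 3·SEM bands,
jackknife errors), not as ad-hoc tolerances. Independent oracles back the
nontrivial kernels: a separately written naive Kabsch superposition (and
MDAnalysis's fitted RMSD) against the batched permutation-corrected RMSD,
hand-evaluated Gaussian mixtures against the KDE, closed-form Hill/energy
values against the fits and the Boltzmann inversion, and analytic dimple
geometry against the deformation profiles.

## Known limitations

* Bead-level only; no atomistic selections, masses or secondary
  structure.
* Frames are treated as exchangeable; autocorrelation-aware error models
  are out of scope (replicates are the independence unit).
* The landscape module is 2D only and does no reweighting.
* Leaflet assignment by z-sign fails for flip-flopping or highly curved
  membranes.
* The Hill fit assumes a monotone cationic titration; anionic or coupled
  multi-site models are not implemented.
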