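# Methods

`hydrashell` reconstructs, at desk scale, the standard computational
workflow for characterising hydrated-dication clusters Ca²⁺(H₂O)_n:
a genetic-algorithm (GA) global search over the cluster potential-energy
surface, hydration-shell and hydrogen-bond analysis of the resulting
minima, and harmonic (RRHO) thermochemistry for finite-temperature
ranking. This note records the models, the numerical choices, and what
the package's tests do and do not demonstrate.

## The potential-energy surface

Quantum-chemical surfaces (DFT/MP2) are out of scope; the shipped
backend is an analytic site–site potential chosen so every pipeline
stage is exercisable in seconds:

* **Water**: 3-site, SPC charges (q_O = −0.8476 e, q_H = +0.4238 e),
  flexible with stiff harmonic restraints
  k_bond (r − r₀)² per O–H bond (k_bond = 4000 kJ mol⁻¹ Å⁻², r₀ = 1.0 Å)
  and k_angle (θ − θ₀)² per molecule
  (k_angle = 400 kJ mol⁻¹ rad⁻², θ₀ = 109.47°).
  Flexible-with-restraints rather than rigid-body parameterization keeps
  minimization and Hessian code uniform in Cartesian coordinates.
* **Dispersion–repulsion**: Lennard-Jones 4ε[(σ/r)¹² − (σ/r)⁶] on O–O
  pairs (ε = 0.6502 kJ/mol, σ = 3.166 Å) and ion–O pairs.
* **Electrostatics**: Coulomb k_e q_i q_j / r over all site pairs of
  distinct molecules, k_e = 1389.35 kJ mol⁻¹ Å e⁻²; the ion is a bare
  +2 e point charge. No cutoffs, no periodicity — clusters are finite
  and all pairs are summed exactly.

**Calibration.** The single free knob is the ion–O σ. Its ε is set
equal to the O–O value; σ was then calibrated by bisection so the
minimized Ca²⁺(H₂O)₁ complex sits at Ca–O = 2.42 Å, inside the
2.38–2.52 Å first-shell window reported for these clusters by
first-principles and diffraction work. The calibrated value,
σ_ion–O = 3.037 Å, is frozen in the `EnergyModel` defaults and echoed
into every run log.

Units are fixed package-wide: Å, kJ/mol, elementary charge, Kelvin.

This surrogate reproduces the right structural physics — first-shell
populations of 6–8, outer shells attached by hydrogen bonds at
realistic distances (mean first-shell Ca–O 2.49–2.53 Å, H-bonded O–O
≈ 2.75 Å across n = 10–18) — but not quantum-level energetics: absolute
binding energies are model-specific, polarization and charge transfer
are absent, and counterpoise corrections are identically zero because
the backend has no basis sets (the counterpoise operation is exact
bookkeeping over supplied fragment energies, ready for a
quantum-chemistry adapter). One known consequence: this potential
saturates the first shell at N₁ = 8 from n ≈ 12 onward instead of
fluctuating between 7 and 8, so the covariation of |E_I/N₁| with the
mean first-shell Ca–O distance that N₁ fluctuations produce in
electronic-structure data is largely absent here (measured Spearman
rank correlation ≈ 0.15–0.4 depending on seed).

## Local minimization

Candidates are relaxed by a hybrid quasi-Newton scheme implemented in
numba-compiled kernels: L-BFGS (history 8, Armijo backtracking) down to
a coarse gradient norm of 0.5 kJ mol⁻¹ Å⁻¹, then eigenvalue-clamped
Newton steps from a finite-difference Hessian (|λ| floored at
0.05 kJ mol⁻¹ Å⁻², factorization reused for up to four steps). The
Newton phase exists because water clusters have nearly flat torsional
modes that stall first-order methods; the hybrid converges a 10-water
cluster to max-gradient 10⁻⁴ kJ mol⁻¹ Å⁻¹ (the default `gtol`) in
~30 ms. Minimization is monotone in energy and idempotent; divergence
to non-finite energy raises an error carrying the last valid iterate.

## Genetic algorithm

A Lamarckian cluster GA: every candidate is locally minimized before it
competes. Defaults (all overridable in `GAConfig`): population 16,
max 400 generations, stall stop after 60 generations without
improvement > 10⁻³ kJ/mol, crossover probability 0.8, equal mutation
weights. Selection is tournament of two with ties to the lower
(better-energy) index, which keeps runs deterministic under a seed.

* **Initialization**: waters placed at uniform-random directions with
  radii in [2.2, 5.5] Å and random orientations, rejecting overlaps
  (O–O < 1.8 Å, ion–O < 1.5 Å); optional seeding from XYZ files of
  earlier runs is supported but never assumed.
* **Crossover**: cut-and-splice — a random plane through the ion splits
  both parents; the child keeps parent A's waters on one side and fills
  to n with parent B's other-side waters nearest the plane. Overlaps
  are repaired by 0.1 Å radial nudges (≤ 100); an unrepairable child is
  retried with a new plane.
* **Mutation** (one per offspring, weight-proportional):
  `rotate_water` (reorient one water in place), `shell_hop` (move one
  water radially by ±1.5–2.5 Å), `twist` (rotate all waters beyond a
  random radius about a random axis).
* **Deduplication**: two minima are duplicates when their energies
  agree within 10⁻³ kJ/mol *and* their sorted ion–O and O–O distance
  vectors agree elementwise within 0.05 Å. The fingerprint is
  rotation/translation/permutation invariant; mirror images share it,
  so enantiomeric minima count once — a documented limitation.

The pool's best entry never worsens (elitism), and identical
(n, model, config) reproduce the pool entry-by-entry. For n = 1–3 the
GA best matches a 10⁵-restart independent multistart oracle to
~10⁻¹² kJ/mol; at n = 6–12 the best structures keep first-shell counts
in [6, 8].

## Hydration shells and hydrogen bonds

The source data this package emulates marks hydrogen bonds graphically
without a numeric rule, so the criterion is explicit and configurable:
donor→acceptor O_d–H···O_a is a bond when O–O ≤ 3.5 Å, H···O_a ≤ 2.6 Å
and the O_d–H···O_a angle ≥ 140°; when both donor hydrogens qualify
toward one acceptor only the larger-angle one counts.

Shell 1 is defined by ion–O ≤ 3.2 Å — the midpoint of the clean gap
between observed first-shell (≤ 2.52 Å) and second-shell (≥ 4.08 Å)
mean distances. Outer shells follow hydrogen-bond *graph* distance
(shell k = k−1 steps from the nearest first-shell water), which
reproduces shell semantics for bridged topologies; waters with no
H-bond path fall back to raw distance bins (≤ 5 Å → shell 2,
≤ 7 Å → shell 3, else unassigned) and are flagged. "Adjacent O–O
distance" is read as the mean over hydrogen-bonded pairs, matching how
adjacency is drawn in structure figures; the nearest-neighbour reading
is the plausible alternative and would shift values slightly.

## Thermochemistry

Normal modes come from a mass-weighted finite-difference Hessian of the
analytic gradient. The central difference (default step 0.005 Å) is
Richardson-extrapolated — H = (4 H(h/2) − H(h))/3 — which removes the
O(h²) truncation term; without it the soft-mode spectrum is not
rotationally invariant at useful step sizes (ZPE of a rotated copy
moved by ~10⁻² kJ/mol; with extrapolation, ~10⁻⁷). Rigid translations
and rotations are projected out exactly (SVD-orthonormalized basis;
linear structures detected by inertia-tensor rank), leaving 3N−6 (or
3N−5) modes; residual negative-curvature modes are counted in
`n_imaginary`, never folded into the ZPE.

RRHO corrections at temperature T: harmonic vibrational energy
(ZPE included), ideal-gas translational and rigid-rotor rotational
terms, pV = RT for enthalpy, and Sackur–Tetrode/rigid-rotor/harmonic
entropies (1 atm, symmetry number 1) for the Gibbs correction.
Frequencies below 10 cm⁻¹ enter entropy terms floored at 10 cm⁻¹ (the
usual quasi-harmonic guard); raw values are always reported. Isomer
ranking uses E_min + ZPE at 0 K and E_min + (G(T) − E_min) at T, each
column relative to its own minimum — finite-temperature re-ranking is
detected exactly on planted two-level fixtures. Because "thermal
correction" is ambiguous between enthalpic and free-energy conventions,
both H and G corrections are emitted.

## Synthetic fixtures

`fixtures.build_fixture` plants ground truth the analysis must recover:
first-shell oxygens on a repulsion-relaxed spherical packing
(octahedral-like at N₁ = 6 yet constructible for N₁ = 7, 8) with
dipoles pointing away from the cation — which geometrically forbids
first-shell–first-shell H-bonds; outer waters placed on their shell
radius at the law-of-cosines polar offset that realises a 2.8 Å O–O
separation along each planted bond, donors reoriented so a hydrogen
points exactly along each bond (angle 180°, ≥ 0.2 Å / ≥ 10° margin over
the criterion). Default shell radii 2.40 / 4.30 / 5.60 Å follow the
observed shell windows. Jitter (default 0.05 Å, Gaussian) is applied
last with rejection sampling: a draw that breaks a planted relation or
creates a spurious one is redrawn, so recovery tests are exact, not
statistical. Fixtures are analysis-stage ground truth only — they are
not minima of any model.

Passing the 200-fixture recovery check therefore shows the analysis is
correct on topologies *within* its stated motif family (N₁ = 4–8,
≤ 2 acceptors per donor, tree-like outer shells) under moderate noise;
it says nothing about exotic bridged topologies or about how well the
GA's physical minima match quantum-chemical structures.

## Problem sizes and reproducibility

Test and acceptance runs use the sizes the analysis targets: the size
series n = 6–18 at the default GA budget (~90 s), the multistart oracle
at 10⁵ restarts for n = 1–3 in the test suite and 2×10⁴ in the
acceptance script (the GA–oracle gap is ~10⁻¹² kJ/mol either way).
Every random choice flows from one integer seed; per-size GA seeds are
derived arithmetically and logged. Bundles contain no timestamps and
use fixed numeric formatting, so identical config + seed reproduce
byte-identical output — asserted in the tests.

## Known limitations

* No polarization/many-body terms; energetics are not quantitative
  against electronic-structure references (qualitative trends only).
* First-shell saturation at N₁ = 8 (see above) weakens the
  E_I/N₁-vs-distance rank correlation the quantum data shows.
* The distance fingerprint cannot distinguish enantiomers.
* Harmonic treatment of nearly free torsions; the 10 cm⁻¹ entropy floor
  is a guard, not a cure.
* The H-bond and shell cutoffs are conventions; borderline waters
  (e.g. a third-shell water near 5–6 Å) can classify differently than
  a hand-drawn figure would.
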