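# Methods

This note documents the models, conventions, and numerical choices
behind cipoc, and what its synthetic test surfaces do and do not
establish about real screening campaigns.

Units are fixed globally and never passed as arguments: Å, kcal/mol,
cm⁻¹, K, atm, amu. Atomic masses come from a bundled table of IUPAC
standard atomic weights (not most-abundant-isotope masses); covalent
radii follow Cordero, van der Waals radii Bondi.

## Transition-state templates and diversification

A template holds two substrate fragments frozen at a coupling-TS-like
geometry — a malonate-like nucleophile and a nitroalkene-like
electrophile, joined by a partially formed C–C bond — plus two
catalytic-site placeholders (HBD and HBA). Sites are *derived*
geometry: each site is anchored to one fragment by a rule
`position = contact + standoff · unit(contact − center)`, where the
contacts are the fragment's H-bond contact atoms (nitro oxygens on the
electrophile, carbonyl oxygens on the nucleophile), the center atom
fixes the outward direction, and the standoff defaults to 2.0 Å (a
typical heavy-atom H-bond contact distance). Recomputing sites from
anchors after every operation is what makes the three diversification
moves exactly consistent:

* **Binding mode.** BMA anchors the HBD site to the electrophile's
  nitro group and the HBA site to the nucleophile; BMB exchanges the
  assignments. Because positions are recomputed by the same anchoring
  rule on the other fragment, the swap is an exact involution.
* **Enantiotopic face.** The electrophile is reflected across the
  plane spanned by the forming-bond axis and the electrophile anchor's
  center atom (the nitro nitrogen). This plane choice keeps the forming
  bond and the nitro attachment in-plane while inverting the approach
  chirality; a degenerate (collinear) construction raises a geometry
  error. Applying the reflection twice restores coordinates to machine
  precision.
* **Rotamer.** The nucleophile fragment (and its anchored site) is
  rotated rigidly about the forming C–C axis. The nucleophile's forming
  atom lies on the axis, so the forming-bond length is invariant by
  construction.

`enumerate_variants` takes the Cartesian product
{BMA, BMB} × {Re, Si} × {0°, step, …, 360° − step} in deterministic
(mode, face, angle) order. The default step is 60°, i.e. 6 rotamers and
24 variants per model; the 2 × 2 × 6 factorization is the natural
reading of the three successive diversifications, and the step is the
coarsest one consistent with a 24-structure enumeration and with
3-fold torsional chemistry about an sp³–sp³ forming bond. Only the
total count, not the increment, is externally fixed, so the step is a
parameter.

## Catalophore model and matching

A CGM carries typed features (HBD, HBA, AromaticCentroid) with
per-feature tolerance radii (default 1.0 Å, per-kind overridable) and
excluded-volume spheres at every substrate heavy atom with radius
0.8 × vdW — a deliberately lenient steric filter, since candidate
catalysts only need to avoid gross overlap with the substrates.
Feature perception on conformers requires connectivity: HBD is every
hydrogen on N/O (position at the H, direction along the would-be
H-bond), HBA every N/O with formal charge ≤ 0, AromaticCentroid the
centroid of every all-aromatic-bond ring. Feature directions are
perceived but not scored in this version; distance-only matching is
the documented extension point.

Matching enumerates all injective, kind-preserving correspondences of
size k, min_match ≤ k ≤ |CGM| (k = |CGM| included by default:
although the protocol's "partial matching" is defined as two-to-fewer-
than-all features, discarding a *complete* match from a screen is never
desirable; `allow_full=False` reproduces the literal partial-only
policy). Each correspondence is superposed by the SVD least-squares
rigid fit with determinant correction — a proper rotation always, since
silently mirroring a candidate would invert the stereochemistry the
screen exists to probe. Acceptance requires every matched feature
within its tolerance sphere after the fit and no conformer heavy atom
inside an exclusion sphere.

**Degenerate fits.** Two matched features (or any collinear set) leave
the least-squares rotation free up to a spin about the matched-segment
axis. The spin moves no matched point — RMSD and tolerance checks are
spin-independent — but it sweeps the rest of the molecule around the
axis, so a steric check at one arbitrary spin angle would make
acceptance depend on the conformer's input frame. The contract is
therefore existential: a degenerate correspondence passes the steric
filter iff *some* spin angle (2° scan) clears the excluded volume.
This restores exact rigid-motion invariance of (acceptance, n_matched,
RMSD); only the stored transform's gauge is conventional.

Correspondence enumeration is capped (default 10⁵ per conformer) with
a loud warning; hits are ranked lexicographically by n_matched
(descending), feature RMSD (ascending), then conformer energy, with
stable ties.

## Conformer libraries

The stochastic search perturbs all rotatable torsions (acyclic,
single, non-aromatic bonds between non-terminal atoms, identified by
bridge detection) with uniform random angles from a seeded PCG64
generator, rejects geometries with any nonbonded pair closer than
0.7 × the covalent-radius sum, rejects re-drawn geometries (aligned
heavy-atom RMSD < 0.01 Å to an accepted conformer), scores survivors
with the energy backend, and stops at the iteration limit or after a
run of consecutive rejections (both limits default 1000). No torsional
minimization is performed; conformational wells are covered by
sampling density, and the library is sorted by energy.

Duplicate pruning is a separate, post-search pass: a greedy sweep in
ascending energy keeps a conformer iff its aligned heavy-atom RMSD to
every kept conformer is ≥ 0.25 Å, making the lowest-energy member of
each cluster the representative. The 0.25 Å threshold applies to heavy
atoms after rigid alignment with identity atom correspondence; no
graph-automorphism symmetry matching is attempted (a documented
limitation for molecules with topologically equivalent heavy atoms).
Keeping the in-search duplicate criterion much tighter than the
library threshold matters: pruning at 0.25 Å *during* sampling thins
the ensemble to ~60°-spaced rotamers and can leave torsional wells
unvisited, while pruning after the search preserves both coverage and
the final library's separation guarantee.

The QM shortlist is the union of the 20 lowest-energy conformers and
all catalophore-matching conformers, energy-ordered and deduplicated.

The bundled `ToyForceField` (hard-sphere quadratic clash penalty plus
3-fold cosine torsions) is adequate for exercising pipeline logic —
deterministic, exactly rigid-motion invariant, three staggered wells
per torsion — and for nothing else; any callable
`(molecule, coords) → kcal/mol` with those invariances can replace it.

## Thermochemistry

Standard ideal-gas RRHO at T (default 298.15 K) and P (default 1 atm,
the Gaussian-convention standard state; no 1 M solution correction):
Sackur–Tetrode translation, classical rigid rotor from the principal
moments of inertia (monoatomic → zero; linear detected by a 1e-4 Å
collinearity test), harmonic vibrations, R·ln(multiplicity) electronic
entropy. The symmetry number defaults to 1 (chiral, asymmetric
species) and is overridable.

The quasi-harmonic correction raises every wavenumber below the floor
(default 100 cm⁻¹, strict inequality — a 100 cm⁻¹ mode is untouched)
to the floor **for the vibrational entropy only**; ZPE and thermal
enthalpy use raw wavenumbers. The floor exists to tame the ln(ν̃)
divergence of harmonic entropy for soft modes; since a floored mode
has lower entropy, flooring can only raise (or preserve) G.
`qh_apply="all"` extends the floor to all vibrational terms, and a
vanishing floor recovers plain RRHO. Transition-state records must
carry exactly one discarded imaginary mode (validation error
otherwise); imaginary modes never enter any sum. G is assembled as
E_elec + H_corr − T·S_total, so the identity holds to machine
precision on every result. Physical constants are the exact SI values
(h, c, k_B, N_A); R = 1.987204259 × 10⁻³ kcal mol⁻¹ K⁻¹.

## Selectivity

ee is computed from Boltzmann populations over the **full** supplied
TS ensemble (a two-member ensemble reduces exactly to
100·tanh(ΔΔG‡/2RT)), with a min-shifted, overflow-safe softmax.
"Racemic" is declared when |w_R − w_S| < 1e-9; a single-outcome
ensemble returns ee = 100 with a degenerate-ensemble warning.
Activation free energies are plain differences against the summed
free energies of the separated starting materials. No Curtin–Hammett
kinetics beyond TS populations is modeled.

## Distortion/interaction analysis

Caller-supplied energies only (any level of theory; electronic
energies are the conventional input): ΔE_dist,i = E_distorted,i −
E_relaxed,i per fragment, ΔE_int = E_assembly − Σ E_distorted, and
ΔE_total assembled as Σ ΔE_dist + ΔE_int so the sum rule is exact in
floating point. A fragment whose relaxed energy exceeds its distorted
energy by more than 1e-6 kcal/mol is rejected as inconsistent input.
Path profiles require strictly monotone coordinates;
catalyst-to-catalyst comparisons are computed component-wise and are
exactly antisymmetric. Decomposition of ΔE_int into
electrostatic/charge-transfer/Pauli terms is out of scope.

## Synthetic test surfaces

The fixtures emulate a screening campaign with known ground truth, not
chemistry. The reference template uses idealized planar fragments with
a 2.2 Å forming C–C distance (within the 2.19–2.26 Å range typical of
this coupling TS); its default CGM has 3 features (1 HBD + 2 HBA from
the double-contact acceptor site, mirroring dual-H-bonding catalyst
motifs) and 10 exclusion spheres. Planted libraries contain, in
deterministic largest-remainder proportions (default ¼ each):

* **matchers** — rigid molecules whose hydroxyl H and carbonyl O's sit
  exactly on the CGM feature points (≤ 0.12 Å per-atom jitter, then a
  random rigid motion), backbone arced away from the excluded volume;
* **decoy-geometry** — correct feature kinds (one ammonium-type N⁺–H
  donor, one carbonyl acceptor) at a hopeless 15 Å separation, so no
  feature pair can fit any CGM pair within tolerance;
* **decoy-kind** — two donors and no acceptor (protonated nitrogens
  are charge-excluded from HBA perception);
* **inert** — methane-like, featureless.

Rigidity is achieved by making every skeleton bond a double bond —
cumulated backbones are chemically absurd but guarantee that the
planted geometry is the molecule's *only* accessible conformation,
which is exactly what the recovery/rejection ground truth requires.
Consequently, passing the planted-library criteria demonstrates the
correctness of the matching and pipeline logic, **not** screening
power on flexible, realistic catalysts: real campaigns depend on
conformer-ensemble quality and energy-model accuracy that the toy
backend does not provide.

Test and acceptance runs use desk-scale problem sizes — 12-molecule
libraries, ≤ 4-feature queries, ≤ 6-feature conformers for
brute-force cross-checks, 100-iteration searches on a one-torsion
fixture — chosen so every brute-force oracle (dense rotation grids,
exhaustive correspondence enumeration, 1° torsion scans, 50-digit
decimal Boltzmann sums) stays exact and fast.

## Reproducibility conventions

All randomness flows from explicit integer seeds through NumPy PCG64
generators; the pipeline derives one child seed per catalyst via
SeedSequence(base, index) so that library order, not iteration order,
determines each catalyst's stream. Fixed config + seed gives
byte-identical hit-table bodies and SDF exports; the provenance header
hashes the computation-determining parameters (seed, limits,
thresholds) and deliberately excludes file paths.
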