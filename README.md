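# cipoc

A catalophore-based 3D virtual-screening toolkit for designing
bifunctional organocatalysts, built around the stereodetermining C–C
coupling of a malonate nucleophile with a trans-β-nitroalkene (the
Michael addition behind γ-aminobutyric-acid-drug precursors such as
Baclofen intermediates).

The idea is "inside-out" catalyst discovery: instead of docking
catalysts one by one, start from a **theozyme** — an idealized
transition-state model surrounded by bare catalytic groups (an H-bond
donor engaging the nitro group, an H-bond acceptor/base engaging the
nucleophile) — and turn it into a **catalophore** (catalytic group map,
CGM): a pharmacophore-style 3D query of typed features with tolerance
radii plus excluded volume. Conformer libraries of candidate catalysts
are then screened for geometries that can *present* those catalytic
groups in the transition-state arrangement, and the shortlisted
conformers are handed to quantum chemistry for activation-barrier and
selectivity evaluation.

The toolkit implements the full desk-scale protocol:

| stage | module | what it does |
|---|---|---|
| template diversification | `cipoc.theozyme` | enumerate binding modes (BMA/BMB) × enantiotopic faces (Re/Si) × rotamers about the forming C–C bond — 2 × 2 × 6 = 24 templates per model at the 60° default |
| catalophore query | `cipoc.catalophore` | CGM construction from a theozyme, HBD/HBA/aromatic feature perception, partial 3D matching (≥ 2 features) with least-squares superposition, steric veto, lexicographic hit ranking |
| conformer libraries | `cipoc.conformers` | seeded stochastic torsional search (iteration/rejection limits default 1000), 0.25 Å aligned heavy-atom RMSD deduplication, "lowest 20 + matching" QM shortlist |
| thermochemistry | `cipoc.thermochem` | ideal-gas RRHO Gibbs free energies at 298.15 K / 1 atm with the quasi-harmonic floor (wavenumbers below 100 cm⁻¹ raised to 100 cm⁻¹ for the vibrational entropy) |
| selectivity | `cipoc.selectivity` | Boltzmann populations over the TS ensemble; ee% = 100·\|Σw(R) − Σw(S)\|, which for two TSs is 100·tanh(ΔΔG‡/2RT) |
| strain analysis | `cipoc.distortion` | distortion/interaction decomposition ΔE_total = Σ ΔE_dist + ΔE_int, pointwise and along a reaction path |
| orchestration | `cipoc.pipeline`, `cipoc.cli` | the end-to-end screen with seeded, byte-reproducible outputs |
| synthetic surfaces | `cipoc.fixtures` | reference template, planted matcher/decoy libraries, thermochemistry fixtures |

Electronic energies are inputs throughout: a pluggable `EnergyBackend`
contract (with a deliberately simple hard-sphere + cosine-torsion toy
backend) stands where a molecular-mechanics or DFT engine would run, so
the screening logic is testable without one.

## Worked example

Predict the enantiomeric excess from two competing enantiomeric
transition states with quasi-harmonically corrected free energies of
11.6 and 14.4 kcal/mol (a 2.8 kcal/mol gap) at 298.15 K:

```python
from cipoc.selectivity import TSRecord, ee_from_ensemble

res = ee_from_ensemble([TSRecord("(R)-TS", "R", 11.6),
                        TSRecord("(S)-TS", "S", 14.4)])
print(f"ee = {res.ee_percent:.1f}%  major = {res.major}")
for label, w in res.weights.items():
    print(f"  {label}: population {w:.4f}")
```

prints

```
ee = 98.2%  major = R
  (R)-TS: population 0.9912
  (S)-TS: population 0.0088
```

meaning the lower transition state carries 99.1% of the Boltzmann
population and the reaction is predicted to be strongly R-selective.

Run a complete screen on a synthetic 12-catalyst library with three
planted matchers (every output is reproducible from the seed):

```bash
cipoc fixtures --what library --seed 2 --n 12 --out library.sdf
cipoc fixtures --what cgm --out cgm.yaml
cipoc screen --library library.sdf --cgm cgm.yaml --seed 3 --out screen_out/
# -> "3 hit(s); outputs in screen_out/"
```

`screen_out/hits.tsv` ranks the three matchers (all three catalophore
features matched, sub-0.1 Å feature RMSD) and `qm_shortlist.sdf`
contains the conformers a QM engine would refine. Other subcommands:
`cipoc diversify` (24-template enumeration as multi-frame XYZ),
`cipoc thermo` (batch quasi-harmonic Gibbs energies), `cipoc ee`,
`cipoc dia` (distortion/interaction tables).

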