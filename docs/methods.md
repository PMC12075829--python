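# Methods

## Scope and model

`cdftscreen` implements a descriptor-based screening pipeline for
non-covalently bound composite candidates, exercised here on six modeled
poses of a genistein–L-hyoscyamine composite. The pipeline consumes
electronic-structure *summaries* — total energies of the vertical N−1/N/N+1
electron states, frontier-orbital energies, per-atom Hirshfeld charge
triplets, and a thermochemical block — and never runs quantum chemistry
itself: geometry optimization, wavefunction analysis, grid-based surface
analyses (electrostatic-potential maps, reduced-density-gradient
isosurfaces, topological bond-critical-point searches) are upstream
producers whose numeric outputs this package post-processes.

### Global reactivity indices

From vertical state-energy differences IP = E(N−1) − E(N) and
EA = E(N) − E(N+1) (not Koopmans orbital estimates):

- electronegativity χ = (IP + EA)/2, chemical potential µ = −χ
- hardness η = IP − EA, softness S = 1/η
- electrophilicity ω = χ²/(2η), nucleophilicity ε = 1/ω

The *unhalved* hardness convention is the default because it is the one
under which the bundled dataset's printed values are internally consistent
(η = 7.93 − (−0.35) = 8.28 eV for L-hyoscyamine); the halved textbook
variant η = (IP − EA)/2 is selectable via `convention="halved"`. Negative
vertical EA (unbound anion) is accepted unmodified. The identities S·η = 1
and ω·ε = 1 hold at machine precision by construction and are enforced by
property tests.

### Condensed Fukui functions and dual descriptor

With q the atomic *charge*: f⁻ = q(N−1) − q(N), f⁺ = q(N) − q(N+1),
f⁰ = (f⁻ + f⁺)/2, CDD = f⁺ − f⁻. Literature statements of these formulas
often mix charge and electron-population (p = Z − q) conventions, which
flips every sign; the package pins the charge-difference form that makes
Σf⁻ = Σf⁺ = +1 on the bundled tables and labels it in the table metadata.
Atoms are flagged as nucleophilic-attack sites when CDD > +τ and
electrophilic-attack sites when CDD < −τ, with τ = 0.05 e by default —
there is no universal threshold in the literature; 0.05 e is calibrated so
the flagged sets coincide with the sites the reference analysis singles
out, and it is a plain parameter.

### Energetics and thermochemistry

Binding energy BE = E(complex) − Σ E(fragments) over neutral totals.
Totals are only comparable within one level of theory, so every record
carries a mandatory theory label and BE refuses mixed labels — the bundled
dataset re-optimized both parents at the composites' B3LYP/6-31G level for
exactly this reason. The thermochemistry check recomputes S = (H − G)/T
(eV → cal·mol⁻¹ through a single conversion table: 1 Hartree =
27.211386245988 eV, 1 eV = 23.060548 kcal·mol⁻¹) at T = 298.15 K. The
temperature is not stated by the data source; 298.15 K is validated by the
check itself (all six poses close to ≤ 0.003 cal·mol⁻¹·K⁻¹, far inside the
0.1 tolerance used for printed-precision inputs).

Contacts are classified from the optimized contact length: H···O/N ≤ 2.5 Å
→ hydrogen bond, anything ≤ 3.6 Å → van der Waals, else none. The cutoffs
are conventional structural-chemistry values; on the bundled poses they
reproduce the hydrogen-bonded (01/02/04/05) versus dispersion-only (03/06)
split that the upstream isosurface analysis reports.

### Rule-based ADME layer

TPSA (Ertl fragment contributions) and atomic logP (Wildman–Crippen) are
computed from SMILES via RDKit, the reference implementation of both
schemes; H-bond donor/acceptor and rotatable-bond counts, molecular
weight, Lipinski and Veber outcomes likewise. The Martin bioavailability
score is implemented here as an explicit rule table: anions score by TPSA
band (< 75 Å² → 0.85, 75–150 → 0.56, ≥ 150 → 0.11); all other charge
classes score 0.55 with ≤ 1 Lipinski violation, else 0.17. Charge class is
detected from explicit formal charges and defaults to neutral.
Machine-learned endpoints (Pgp substrate, solubility class, GI absorption
class, consensus logP, synthetic accessibility) are consumed as supplied
flags with provenance labels, never recomputed. Composite TPSA/logP are
likewise supplied data: the covalent adduct structures behind those cells
were never published as SMILES, and the package refuses to guess them.

### Screening engine

Hard filters (equality predicates, e.g. Pgp substrate = no) exclude
candidates with the failing filter recorded; surviving candidates are
scored per criterion by directed min–max normalization to [0, 1] (constant
columns map to 0.5, keeping them weight-neutral), combined as Σ wᵢ·sᵢ with
weights normalized to 1, ranked with ties broken by ascending candidate
id, and reported together with the Pareto front (candidates not dominated
on all directed criteria). Min–max normalization makes the ranking
invariant under positive affine transforms of any raw column.

The default criterion set — gap ↑ 0.20, binding energy ↓ 0.20, dipole ↑
0.10, entropy ↓ 0.15, heat capacity ↑ 0.05, TPSA ↓ 0.15, logP ↑ 0.15 — is
explicitly *calibrated to reproduce the reference verdict* (top-2 = poses
02 and 04) and is exposed as configuration, not presented as an objective
utility function. The dipole direction in particular is genuinely
ambiguous in the source argumentation (a high dipole is praised for
hydrogen-bonding ability while the other winner has the lowest dipole);
it is configuration like everything else.

## Bundled reference dataset

The packaged transcription preserves two source defects instead of
repairing them: (1) parent three-state totals are printed only to 3
significant figures (Hartree), so the parent records reconstruct the ion
totals from the printed vertical IP/EA (documented in
`datasets.load_study_bundle`); (2) the hyoscyamine anion-state charge
column sums to −0.910 rather than −1 (the printed f⁺ column shares the
defect), so records are validated with a relaxed ±0.1 charge-sum tolerance
and the normalization invariant is asserted only where the source closes.
One typographically ambiguous TPSA cell is stored as 90.90 Å², the value
consistent with the Ertl fragment sum.

## Synthetic generator

`synthetic.gen_molecule` builds records with *exact* prescribed targets:
ion totals offset from the neutral total by IP/EA, orbital pair separated
by the gap, per-atom charges as a zero-sum uniform baseline plus the
prescribed Fukui profiles (so the charge-difference convention returns
them identically and column sums close exactly), and a thermochemical
block with G = H − T·S. `gen_composite_set` sets the complex total to the
fragment sum plus the prescribed binding energy exactly.
`round_to_printed` emulates table printing (round half away from zero) so
tolerance policies can be tested against rounded data. Synthetic total
energies are drawn from a deliberately modest range (−2000 to −500 eV) so
that state-energy differences recover targets to below 1e−12; real totals
of tens of thousands of eV would leave only ~4e−12 of floating-point
resolution, and the generator models algebraic structure, not realistic
magnitudes. It does not emulate electron densities, geometries, basis-set
effects or correlated noise between states — passing recovery tests shows
the descriptor algebra is implemented correctly, not that the pipeline is
robust to real electronic-structure error.

## Problem sizes and determinism

All computations are desk-scale: 2 parents (30 and 44 atoms of charge
data), 6 composites, screening over ≤ 6 candidates; property batteries use
50 synthetic seeds and 50-candidate Pareto oracles. The full test suite
runs in a few seconds. A single integer seed drives every stochastic
element; reports echo their configuration including the seed.

## Known limitations

- The screening weights are a calibrated, documented choice; different
  defensible weights reorder the non-winning candidates.
- Fukui condensation is only as meaningful as the upstream charge
  partitioning; the package treats charges as given.
- The ADME layer covers only rule-based descriptors; consensus/ML
  endpoints must be supplied.
- No 3-D structure handling: contact classification uses tabulated
  lengths, not coordinates.
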