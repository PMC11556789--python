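# Methods

This note defines the quantities the package computes, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for exact
reproducibility.

## System model

A system is a set of protein chains (residues → heavy atoms with role
labels), monatomic ions (Cl⁻, Na⁺) and 3-site waters in an orthorhombic
periodic box. Coordinates are in Ångström, charges in elementary units.
Role labels are fixed by amino-acid chemistry: `backbone_N`/`backbone_O`
are the amide nitrogen and carbonyl oxygen; `sidechain_N` covers Arg
(NE, NH1, NH2), Lys (NZ), Asn (ND2), Gln (NE2), His (ND1, NE2), Trp (NE1);
`sidechain_O` covers Ser, Thr, Tyr, Asp, Glu, Asn, Gln (and the phosphate
oxygens of phospho-Tyr); `ring_carbon` is the six-carbon ring of Tyr and
Phe only — Trp's fused ring and de-aromatized phospho-Tyr are deliberately
excluded. "Heavy atom" means any non-hydrogen atom; hydrogens are kept in
the topology only where they are needed (water RDFs count all three water
atoms) and never enter contact logic. Internal residue indexing is 0-based;
PDB I/O converts to/from 1-based per-chain numbering. Triclinic boxes are
rejected rather than silently wrapped, and a box is mandatory on input.

Protein charge is counted per chain as (+1 per Arg/Lys, −1 per Asp/Glu,
−2 per phospho-Tyr), His neutral unless a low-pH flag protonates it.
Termini are treated as uncharged; for the 131-residue reference composition
this pins the per-chain charge to +9 and the 8-chain total to +72.

The packaged reference sequence is a **composition-matched synthetic
stand-in** for A1-LCD: the published composition (51 G, 22 S, 11 F, 7 Y,
13 N, 4 Q, 10 R, 2 K, 3 D) fixes 123 of 131 residues; the remaining 8 are
neutral, non-aromatic fillers (4 A, 2 P, 1 T, 1 M) and the ordering is a
frozen shuffle. Composition-level results (charge, aromatic and site
counts) are exact; position-specific analyses on this sequence are not
meaningful.

## Periodic-boundary conventions

All pair distances use the minimum-image convention,
d = |Δ − L·round(Δ/L)| per axis. Re-centering on a chain
(`center_on_chain`) makes the chain contiguous by cumulative minimum-image
steps along its atom order, moves its centroid to the box center, and wraps
every other molecule *as a unit* (chain, water, or ion) into the central
box, so no molecule is ever split by the wrap.

**D<sub>max</sub>** is the largest of the three axis-aligned extents of all
protein atoms. To remove wrap artifacts the measurement is repeated once
per chain, re-centering on each, and the smallest candidate is reported
together with the chain that produced it. Ions and waters are excluded:
the quantity describes the multi-chain protein assembly.

**R<sub>g</sub>** is mass-weighted by default (a flag gives the geometric
variant) and requires a contiguous chain — the function rejects wrapped
input instead of silently unwrapping, and `rg_series` re-centers each chain
before measuring.

**RMSF** superposes each chain (rigid-body least squares on backbone heavy
atoms, Kabsch) onto its time-average structure, refining the average over
two superposition rounds, and reports per-residue Cα fluctuations averaged
over chains. The reference structure is a pinned choice; two rounds are
enough for the iteration to be stationary on rigid or quasi-rigid input.

## Contacts and interaction types

Two residues are in contact in a frame when any in-scope heavy-atom pair is
within the cutoff (default 6.0 Å, minimum image); a residue pair counts
once per frame no matter how many atom pairs qualify. For intra-chain
counts the two nearest sequence neighbours (offset ±1) are excluded; the
offset is configurable since "nearest neighbours" could also be read as
±2. Contact searches use a periodic KD-tree, but because membership is
defined purely by minimum-image distances the result is independent of how
the input is wrapped — per-chain re-centering before contact evaluation (a
common workaround in trajectory tools that measure unwrapped distances) is
a mathematical no-op here. The test suite pins the KD-tree path to a plain
all-pairs 27-image oracle with zero tolerance.

Inter-chain residue pairs (sidechain-heavy scope) are typed from residue
identity alone: {Arg,Lys}×{Asp,Glu} → salt bridge, {Arg,Lys}×{Tyr,Phe} →
cation-π, {Asn,Gln}×{Tyr,Phe} → amino-π, {Tyr,Phe}×{Tyr,Phe} → π-π,
anything else → other. Glu is included in the salt-bridge rule for
generality; the reference composition contains no Glu, so its counts are
unchanged. No angular criteria are applied — the definitions are
distance-only by design. Typed counts are reported per chain (pairs /
n<sub>chains</sub>).

## Ion binding, net charge, bridging

Coordination sites are protein N and O atoms (carbon and sulfur are not
ion-coordination sites). For each ion the governing distance is the
minimum over the selection's atoms; shell bands are **inclusive**:
first shell d ≤ c₁, second shell c₁ < d ≤ c₂. Defaults are the RDF-derived
cutoffs c₁/c₂ = 4.0/6.4 Å for Cl⁻ and 3.0/5.4 Å for Na⁺;
`suggest_shell_cutoffs` can read cutoffs off a measured RDF (first two
local minima after the first two peaks of the 3-bin-smoothed profile) but
is advisory only. Inclusive boundaries make the stated cutoffs act as
closed thresholds; whether the boundary itself binds is configurable in
principle but fixed here and exercised by boundary tests at exactly 4.0
and 6.4 Å.

Binding counts collect **unique ions per selection**: an ion coordinating
several residues or chains of the same selection adds one to that
selection's total. Per-residue values divide by the number of residues of
the selected type. Frame averages are taken per replicate first; reported
uncertainties are standard deviations **among replicates** (n−1
denominator).

Net charge is the exact identity Q(t) = Q<sub>protein</sub> +
N<sub>Na,bound</sub>(t) − N<sub>Cl,bound</sub>(t), with "bound" meaning
within the species' second-shell cutoff of any protein N/O atom. An ion is
**bridging** when protein N/O atoms of ≥ 2 distinct chains lie within its
second-shell cutoff in the same frame; the bridge histogram indexes bound
ions by the number of distinct chains contacted, so its column sums equal
the bound-ion counts by construction.

## RDFs

g(r) is the pair-distance histogram over frames normalized by the
ideal-gas expectation: g(bin) = H(bin) / (Σ<sub>f</sub> N<sub>c,f</sub> ·
ρ<sub>t,f</sub> · V<sub>shell</sub>), with ρ<sub>t</sub> = N<sub>t</sub>/V<sub>box</sub>
per frame and V<sub>shell</sub> = (4π/3)(r₂³−r₁³). Bin width defaults to
0.05 Å; r<sub>max</sub> may not exceed half the smallest box edge;
self-pairs are excluded when the two selections share atoms. Conditional
water RDFs restrict the centers per frame to residues satisfying a partner
condition (e.g. Tyr rings with any Phe ring carbon within 6 Å,
min-distance semantics); frames with no qualifying center contribute
nothing and are tallied separately. A Tyr engaged with several partner
types simultaneously qualifies for each condition independently. Waters
count all three atoms by default (`oxygen_only` restricts to O), and RDF
distances run from each ring-carbon atom, not the ring centroid.

## Synthetic data

The generator produces rigid, self-avoiding chain templates (straight
backbone at 3.8 Å per residue, carbonyls to +y, sidechain ladders to +z)
placed on a wide grid, then realizes planted features constructively:
single-ion plants sit at a prescribed distance outward from a designated
site atom; bridging plants re-orient the involved chains along distinct
axes so their site atoms meet around the ion at the planted distance;
contact plants rotate one chain so the two designated residues meet
sidechain-tip to sidechain-tip at the planted distance. After assembly the
generator **verifies** every intended shell, bridge multiplicity and
contact status against the realized coordinates with plain all-pairs loops
and rejects unrealizable specs; the ground-truth ledger it emits (ion
shells, bridged-chain sets, exact inter/intra contact sets, typed pairs,
D<sub>max</sub>, per-chain R<sub>g</sub>) is therefore exact, and analysis
modules are required to reproduce its integer counts with zero tolerance.

Waters are a uniform background (sufficient for RDF normalization); an
optional depletion mode deletes waters within a stated radius of ring
carbons to emulate the water-withdrawal signature with known magnitude
(g ≡ 0 inside the carved radius when counting oxygens). Default fixture
scale is 8 chains of 12 residues in a 120 Å box — the paper-like 8-chain
geometry at a size where all-pairs verification stays cheap; tests use 2–5
chains. What the generator does **not** emulate: physical conformational
ensembles, realistic water structure, ion-ion correlations, or
thermodynamics of any kind. Passing tests therefore demonstrate that the
*counting and geometry* machinery is exact, not that a given force field
or sampling protocol is adequate.

The two-cluster generator places two rigid chains at a controlled
separation (expected D<sub>max</sub> = span₁ + separation + span₂) and
emits randomly shifted, re-wrapped frames to exercise wrap invariance.
The ideal-gas generator provides the RDF null model; the suite requires
g(r) within 4 Poisson standard errors of 1 in ≥ 99 % of bins (the standard
error per bin is √(2/λ) because each unordered pair enters the ordered
histogram twice).

## Replicates, determinism, outputs

Replicate trajectories are declared explicitly (a list of files in the run
config), never inferred from names. Every generator takes a seed and is
bit-deterministic under it; identical config + seed yields byte-identical
TSV/JSON outputs, and each run writes a log of every default applied. All
tables are TSV; the pipeline summary is JSON.

## Known limitations

- The dense-particle concentration estimate via an ellipsoid model is not
  implemented: the three principal diameters it needs are not recoverable
  from the bounding-box metric alone, so the operation is omitted rather
  than guessed.
- The classifier is validated on composition counts transcribed for 27
  proteins; the phospho-Tyr variant stores published charge-unit counts
  directly rather than re-deriving them from sequence. Flag combinations
  outside the four class patterns return "indeterminate" instead of a
  guessed class, and known composition/behaviour mismatches (e.g. a
  screening-class protein with reentrant-like composition) are reported,
  not special-cased.
- Interaction typing is residue-identity + distance only; no geometric
  π-stacking or hydrogen-bond criteria.
- Orthorhombic boxes only; no electrostatics, free energies, or simulation
  engines of any kind.
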