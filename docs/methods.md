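# Methods

This note records the models, conventions and numerical choices behind
`thermotraj`, and what the synthetic-trajectory tests do and do not
establish about real molecular-dynamics data.

## Scope and model of the data

The package analyzes saved coordinate frames of a solvated protein
simulation; it does not run dynamics. A `Topology` binds atom identities
(names, elements, Bondi van der Waals radii, masses) to residues and named
selections (protein, backbone = N/CA/C/O, side chain, water, ions); a
`Trajectory` is an ordered frame list over one topology with strictly
increasing times (stored in ps, reported in ns). Bonds are inferred
geometrically from the reference coordinates: each hydrogen bonds to its
nearest heavy atom within 1.3 Å, heavy atoms within 1.9 Å of each other in
the same residue are bonded, and across residues only the peptide
C(i)–N(i+1) bond (≤ 2.0 Å) is recognized. Bonds are used solely for
donor–hydrogen lookup and main-chain/side-chain assignment of hydrogens,
so this inference is exact for every input the readers accept; residue
templates would add nothing for these uses.

Residue chemistry: charged = {Arg, Lys, Asp, Glu}, polar = {Gln, Asn, Ser,
Thr, Tyr, Cys}, hydrophobic = {Ala, Ile, Leu, Phe, Val, Pro, Gly, Met,
Trp}. Histidine belongs to none of these (its charge is pH-dependent) and
is classified "other"; for surface-area partitioning "hydrophilic" means
every non-hydrophobic protein residue, which makes the hydrophobic and
hydrophilic areas sum exactly to the total. Unknown residue names classify
as "other" with a warning rather than aborting, so chemically modified
residues survive a run.

## Deviation metrics

RMSD: each frame's selection (default backbone) is rigidly superposed onto
the reference selection by the Kabsch algorithm (SVD with reflection
correction, unweighted — the common backbone-RMSD convention), then the
root-mean-square deviation is taken over the same selection. Summary
statistics use a fractional "converged window", default the final 75 % of
frames (25–100 %), since early frames of production runs still relax; the
window is configurable per run.

RMSF: every frame is aligned onto the initial structure using the backbone,
then per-atom fluctuations are taken about the atom's time-mean position
(the standard `atomicfluct` convention) and averaged within each residue
over the selected atoms. An `initial_structure` reference mode is provided
for comparison with tools that measure deviation from the starting
coordinates instead of the mean; the mean-position mode is the default
because the time-mean is the variance-minimizing reference and the two
differ only by a positive offset that would bias region thresholds.

Radius of gyration is mass-weighted about the weighted centroid (the VMD
convention); an unweighted mode exists.

## Solvent-accessible surface area

Shrake–Rupley: a deterministic golden-spiral (Fibonacci) point set —
default 960 points — is placed on each atom's solvent-expanded sphere
(Bondi radius + 1.4 Å probe; hydrogens included at 1.2 Å when present,
excludable by flag); a point is buried if it falls strictly inside any
neighbor's expanded sphere, and the exposed fraction scales the sphere
area. Neighbor search uses a k-d tree. Only protein atoms form the surface
and occlude; waters and ions are excluded from both, since the quantity of
interest is the protein's exposure to solvent, not instantaneous water
packing. The estimator is within 1 % of the closed form for an isolated
sphere and within 2 % of the two-sphere spherical-cap solution at 960
points; doubling the point count twice changes a 50-atom system's total by
under 1 %.

Aggregation sums per-residue areas into hydrophobic/hydrophilic classes
(reported in nm², i.e. Å²/100) and over the catalytic set (default
residues 473, 510, 642 — nucleophile, general acid/base and
transition-state stabilizer of the target enzyme — configurable). The
catalytic component is reported in Å²: it covers three residues, so the
atomic scale is the readable one, and keeping it out of the nm² columns
avoids implying it participates in the class additivity. Per-frame total
SASA values are histogrammed with 2 nm² bins whose edges sit on even
integers, so centers fall on odd integers; the modal bin is the "major
peak" (ties report the lowest center and set a flag).

## Interaction detection and occupancy

Hydrogen bonds: donors are N/O atoms with at least one bonded hydrogen
(one candidate per hydrogen), acceptors all N/O atoms; water oxygen is
donor (twice) and acceptor. A candidate is present in a frame when the
donor–acceptor distance is **≤ 3.5 Å (inclusive)** and the angle at the
hydrogen (D–H–A) is **> 120° (strict)** — "maximum cutoff" is read as
attainable, "larger than" as exclusive. Intra-residue pairs are excluded
(as in the standard tools); i→i±1 backbone pairs are kept. Water–water
pairs are never enumerated. Candidates sharing (donor atom, acceptor atom)
but differing in hydrogen are redundant: the highest-occupancy one is kept,
ties broken deterministically by lowest hydrogen index. MM/MS/SS
classification calls a side main-chain when the participating heavy atom
is N/CA/C/O or the hydrogen rides on one; chemical-class pairs are
symmetric with any pairing outside the four named combinations (including
anything involving "other") counted as "other", which is why the four
chemical columns do not sum to the total. Protein–water records carry
M-water/S-water (main- or side-chain protein atom) and the protein
residue's class. Mean per-frame category counts equal the sum of the
member records' occupancy fractions.

Salt bridges: Asp OD1/OD2 and Glu OE1/OE2 against Arg NE/NH1/NH2 and Lys
NZ, present when the O–N distance is **< 4 Å (strict)**. All atom
combinations of a residue pair are evaluated; the unique record keeps the
best atom pair by occupancy and reports its mean ± sd distance over formed
frames, alongside a union occupancy (any atom pair in range) for
comparison. The ε-oxygen names are used for glutamate — its side-chain
oxygens are OE1/OE2; δ-oxygens exist only on aspartate.

Hydrophobic contacts: the designated carbon set {C, CA, CB, CD, CD1, CD2,
CE, CE1, CE2, CE3, CG, CG1, CG2, CZ, CZ2, CZ3, CH2} across two residues
within **≤ 4 Å (inclusive)**; any number of in-range carbon pairs gives one
presence bit per residue pair per frame. Backbone C/CA of sequence
neighbors are always within range, so same-residue and |Δseq| ≤ 1 pairs are
excluded — without this the statistics are swamped by trivial adjacencies.
The literature's 3.9 Å carbon–carbon cutoff is available by configuration.
By default all residues' designated carbons participate; a flag restricts
to hydrophobic-class residues.

Occupancy is 100 × frames-present / frames over the full trajectory by
default (interaction statistics are conventionally quoted over the whole
production run), with an optional converged-window restriction. Lifetime
bins are right-inclusive: short (0,10]%, substantial (10,90]%, long
(90,100]%. The stable-interaction filter keeps occupancy **strictly above**
50 %.

Differential classification across ordered conditions (reference first)
rates each interaction present (above the filter) in every condition:
*comparable* when the max–min spread is within 10 points; otherwise
*maintained* when the minimum stays at or above 80 %; otherwise *weakened*
when occupancy decreases strictly along the condition order; otherwise
*variable*. Present in the reference but not everywhere → *lost*; absent
from the reference but present elsewhere → *gained*. The precedence is
deliberate: a high-floor but tightly clustered profile reads as
"comparable", and a decreasing profile that never leaves the 80 % floor
reads as "maintained" rather than "weakened". The 10-point comparability
tolerance and 80 % floor are package choices (the qualitative notions they
quantify are not standardized) and are configurable.

## Regions and statistics

Thermal-sensitive regions are called on ΔRMSF (test condition minus
reference) rather than raw RMSF: the question is where flexibility
*increases* with temperature, and differencing removes intrinsic
flexibility common to all conditions (an absolute mode is available).
Residues with Δ ≥ 0.5 Å form runs; runs separated by ≤ 1 sub-threshold
residue merge; merged regions shorter than 3 residues are dropped; the
first and last 5 residues are ignored because unrestrained termini
fluctuate for reasons unrelated to thermal sensitivity. A region's flag is
"high" when its maximum Δ reaches 1.0 Å, else "moderate". All five numbers
are configurable.

The one-way ANOVA (scipy's F test plus degree-of-freedom bookkeeping,
α = 0.05) compares per-frame metric values between conditions. Treating
correlated frames as independent observations overstates the effective
sample size; the convention is retained for comparability with common
practice and the caveat stands — the p-values are descriptive, not
inferential.

## Synthetic ground truth

The generator builds an extended-chain peptide with idealized geometry:
Cα atoms 3.8 Å apart, side chains zigzagging away from the backbone at
1.5 Å steps, PDB-standard atom names, explicit hydrogens on all donors,
waters on a grid ≥ 4 Å from the protein, and an optional parked Ca²⁺. The
layout guarantees unambiguous bond inference and a contact/H-bond-free
baseline, so every detected interaction in a fixture is either designed or
deliberately provoked.

Trajectories add per-atom isotropic Gaussian jitter (per-residue σ, default
0.15 Å, times a condition "temperature factor") to the reference, so
per-residue RMSF has the closed-form expectation σ√3. Interaction
schedules use exact-count membership: a seeded permutation picks exactly
round(occupancy × n_frames) frames in which the partner atom (and the
hydrogen, for H-bonds, collinear at 2.9 Å; 3.2 Å for salt bridges; 3.8 Å
for contacts) is placed in range relative to its jittered anchor, and 6 Å
away otherwise. Recovery tests are therefore exact rather than binomial; a
Bernoulli mode exists for stress testing. Schedules sharing a moved atom
are rejected as infeasible. Condition sub-seeds derive from the study seed
and a CRC of the condition label, so runs are reproducible byte for byte.

What this emulates: per-residue fluctuation amplitudes scaling with
temperature, designed interaction occupancies, planted flexible regions,
water shells, ion presence/absence. What it does not: force-field physics,
correlated dynamics, realistic water structure, or frames that are jointly
physical (scheduled side-chain tips teleport). Passing recovery tests
demonstrates that the *measurement* pipeline is correct, not that any
biological conclusion transfers; on real trajectories the occupancies and
regions are estimates subject to sampling noise the synthetic schedules
deliberately remove.

## Numerical and I/O choices

- Neighbor searches use `scipy.spatial.cKDTree`; correctness is pinned by
  exhaustive all-pairs oracles in the test suite (identical presence bits).
- Boundary comparisons follow the stated inclusivities exactly; test
  fixtures place boundary distances axis-aligned so the values are exact in
  floating point.
- Trajectory formats are text-only (multi-model PDB and an `xyz_frames`
  dialect: header `natoms nframes`, then per frame a comment line and
  `natoms` coordinate rows at 10⁻⁴ Å). Binary formats (DCD/NetCDF) are out
  of scope; conversion is the user's responsibility.
- PDB reading is fixed-column; altLoc keeps 'A' or blank with a warning;
  missing element fields fall back to digit-stripped name prefixes.
- All result tables are CSV with 4-decimal floats and documented sort
  orders; reports embed a JSON echo of the fully resolved configuration.
  Two runs on identical inputs are byte-identical.
- Analysis problem sizes in the acceptance script (30-residue peptides,
  100–2000 frames, SASA on a frame stride) were chosen as the smallest
  sizes at which every designed quantity is recovered at its stated
  tolerance with margin.

## Known limitations

- The ANOVA pseudo-replication caveat above.
- SASA treats ions as absent from the surface; systems where a bound ion
  shields real surface will read slightly high around the site.
- Hydrophobic-contact records name the single most frequently in-range
  carbon pair; residue pairs whose contact migrates between carbon pairs
  keep full occupancy but the named atoms are representative only.
- The differential caller compares occupancies condition-wise and knows
  nothing about time: an interaction that drifts within one trajectory is
  summarized by its single occupancy number.
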