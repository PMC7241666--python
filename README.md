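# thermotraj

Post-simulation thermostability profiling of protein molecular-dynamics
trajectories, written for studies like the barley limit dextrinase (HvLD)
problem: a brewing enzyme that loses activity at mashing temperatures, whose
stability determinants are probed by comparing trajectories simulated at
several temperatures with and without a structural Ca²⁺ ion.

The package takes a protonated reference structure (PDB) and coordinate
trajectories (multi-model PDB or a plain-text `xyz_frames` dialect) per
condition, and computes:

- **Global deviation metrics** — backbone RMSD after Kabsch superposition
  onto the initial structure, mass-weighted radius of gyration
  R_g = √(Σ mᵢ|rᵢ−r̄|²/Σ mᵢ), and per-residue RMSF, each with
  converged-window (default 25–100 %) mean ± sd.
- **Solvent-accessible surface area** — Shrake–Rupley with a 1.4 Å probe
  and a deterministic 960-point golden-spiral set, aggregated into
  hydrophobic / hydrophilic / catalytic classes (hydrophobic + hydrophilic
  = total by construction) and a per-frame distribution with its modal bin.
- **Hydrogen bonds** — donor–acceptor distance ≤ 3.5 Å and D–H–A angle
  > 120°; redundant candidates sharing a donor/acceptor pair but differing
  in hydrogen are deduplicated keeping the highest occupancy; records are
  classified main-chain/side-chain (MM/MS/SS), by residue chemistry
  (chr–chr, pho–pho, phi–phi, pho–phi), and protein vs water partner.
- **Salt bridges** — acidic O (Asp OD1/OD2, Glu OE1/OE2) to basic N
  (Arg NE/NH1/NH2, Lys NZ) strictly under 4 Å; atom pairs per residue pair
  collapsed to the highest-occupancy one, reported with mean ± sd distance.
- **Hydrophobic contacts** — designated carbon atoms within 4 Å, one
  presence bit per residue pair per frame, sequence-adjacent pairs excluded.
- **Occupancy bookkeeping** — occupancy = 100 × frames-present / frames;
  lifetime bins short (0,10]%, substantial (10,90]%, long (90,100]%;
  a strict >50 % filter for the stable-interaction tables; and
  cross-condition differential calls (comparable / maintained / weakened /
  lost / gained).
- **Thermal-sensitive regions** — ΔRMSF (hot − reference) segmented at
  0.5/1.0 Å thresholds with gap-merging, minimum length, and terminus
  exclusion; plus one-way ANOVA on per-frame metrics between conditions.

A first-class synthetic-data module generates toy peptide topologies and
multi-condition trajectories with *designed* ground truth (exact-count
interaction schedules, per-residue fluctuation amplitudes that scale with a
temperature factor, planted flexible regions, a water shell, optional
Ca²⁺), so every stage of the pipeline is testable without cluster-scale MD.

## Worked example

```python
from thermotraj import synthetic as syn
from thermotraj.interactions import detect_salt_bridges, unique_salt_bridges
from thermotraj.geometry import rmsf_profile

seq = ["MET", "LYS", "ASP", "SER", "LEU", "ARG", "GLU", "VAL", "THR", "ALA",
       "GLY", "PHE", "ASN", "ILE", "ASP", "ARG", "SER", "LEU", "GLU", "LYS"]
cold = syn.ConditionSpec("298K", 1.0, schedules=[
    syn.InteractionSchedule("saltbridge", (3, "OD1"), (6, "NH1"), occupancy=95.0),
])
hot = syn.ConditionSpec("343K", 1.5, schedules=[
    syn.InteractionSchedule("saltbridge", (3, "OD1"), (6, "NH1"), occupancy=62.0),
])
spec = syn.SyntheticSpec(sequence=seq, n_frames=500, seed=7,
                         conditions=[cold, hot])
topology, reference, trajectories, truths = syn.generate_study(spec)

for label, traj in trajectories.items():
    for b in unique_salt_bridges(detect_salt_bridges(traj), topology):
        if b.pair_label == "D3-R6":
            print(f"{label}: {b.pair_label} ({b.acidic_atom}-{b.basic_atom}) "
                  f"occupancy {b.occupancy:.1f}%, "
                  f"distance {b.mean_distance:.2f} +/- {b.sd_distance:.2f} A")

rmsf_cold = rmsf_profile(trajectories["298K"])
rmsf_hot = rmsf_profile(trajectories["343K"])
print(f"mean backbone RMSF 298K: {rmsf_cold.values.mean():.3f} A, "
      f"343K: {rmsf_hot.values.mean():.3f} A")
```

prints

```
298K: D3-R6 (OD1-NH1) occupancy 95.0%, distance 3.20 +/- 0.00 A
343K: D3-R6 (OD1-NH1) occupancy 62.0%, distance 3.20 +/- 0.00 A
mean backbone RMSF 298K: 0.256 A, 343K: 0.383 A
```

The Asp3–Arg6 bridge was scheduled at 95 % / 62 % occupancy in the two
conditions and the detector recovers both exactly (the scheduler places the
basic nitrogen 3.2 Å from the acidic oxygen in exactly the designed number
of frames). The mean backbone RMSF rises by the designed ×1.5 temperature
factor.

## Command line

```sh
thermotraj synth   --spec study.yaml --seed 7 --out fixtures/
thermotraj analyze --config run.yaml --out report/
thermotraj compare --runs report/298K --runs report/343K --out cmp/
```

`analyze` writes per-condition CSV tables (RMSD/R_g/SASA series and
summaries, hydrogen-bond records and category means, salt-bridge and
contact records, monitored distances, RMSF profiles) plus cross-condition
ANOVA, differential interaction calls, and region calls, along with a JSON
echo of every resolved parameter. Re-running with the same inputs produces
byte-identical reports.

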