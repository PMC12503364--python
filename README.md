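# hemegate

Post-processing and statistical analysis of hemoglobin molecular-dynamics
trajectories, focused on the questions that distinguish fish from mammalian
deoxyhemoglobin (DHb) at low pH: does the distal histidine (HisE7) swing out
of the heme pocket, how does the proximal bond and heme doming respond to
HisE7 protonation, how stable are the α1–β2 interfacial contacts that guard
tetramer disassembly, and how solvent-accessible is the heme pocket?

It is a library for structural-bioinformatics work on globins — anyone with
a PDB topology, replicate trajectories (XTC/TRR/DCD/multi-model PDB) and a
site map assigning Perutz helical notation (E7, F8, E11, CE4, C6, C7, FG4,
G1, G4, …) to residues can run the full battery. A synthetic-trajectory
generator with planted ground truth makes every stage testable without any
simulation data.

## What it computes

- **Swing-out events** — a chain-replicate trace counts as an event when the
  HisE7 Nε–Fe distance exceeds 7 Å (0.7 nm) after a 1 ns equilibration
  cutoff. Per trace: first-passage time, all excursions, and whether the
  residue returned down (≤ 7 Å for a ≥ 5 ns dwell). Event counts are
  corrected for total simulation time; swing-out times are normalized for
  within-treatment length differences (to the longest replicate) and
  between-treatment differences (to a reference total time):
  t_norm = t · (T_longest / T_replicate) · (T_ref / T_treatment).
- **Heme geometry** — the Fe–L1 (HisF8 Nε–Fe) distance averaged over the
  1–133 ns window, pooled per chain class (α1+α2, β1+β2); the signed iron
  displacement |Fe − centroid(4 pyrrole N)|, positive toward the proximal
  histidine (T-state-like doming); aromatic stacking descriptors (centroid
  distance, interplanar angle, offset) with parallel-displaced / T-shaped
  classification.
- **α1–β2 interface** — four canonical atom-pair contacts: Asp(α1G1) CG →
  Asn(β2G4) ND2, Tyr(α1C7) CZ → Arg(β2C6) CZ, Arg(α1FG4) CD → Arg(β2C6) CB,
  and the bovine-only Thr(α1C6) OG → Arg(β2C6) CZ hydrogen bond (a
  trout-like Ala at α1C6 removes it, leaving 3 sites). Per-replicate
  distance maxima, plus local backbone RMSD (N, CA, O of the six interface
  residues, Kabsch superposition on the selection itself) with its OLS
  drift slope.
- **SASA** — Shrake–Rupley solvent-accessible surface area of the E11 pocket
  residue and the heme moiety, computed in the context of protein + heme
  atoms only, averaged over 1–133 ns.
- **Statistics** — one-way ANOVA with Tukey HSD pairwise comparisons,
  unpaired t-tests (Student or Welch), simple linear regression; all
  implemented from the standard formulas and cross-checked against
  scipy/statsmodels in the test suite.

All internal lengths are nm (the 7 Å threshold is stored as 0.7 nm);
stacking descriptors are reported in Å as the ring-geometry literature does.

## Worked example

`examples/05_full_pipeline.py` generates the default synthetic system —
five replicates of unequal length (135–150 ns, 0.2 ns frames), two α and
two β chains, with 3 of the 10 α-chain traces planted to swing out (one
returning down), one interface site-2 excursion to 1.15 nm, and a monotone
E11 burial schedule — and runs the full pipeline on it:

```
chain-replicate traces analyzed: 10
swing-out events: 3 raw, 3.00 time-normalized
returns to the down position: 1
mean normalized swing-out time: 41.6 ns
pooled Fe-L1 mean: alpha 0.2130 nm, beta 0.2088 nm
iron displacement (alpha mean): 0.0350 nm
largest site-2 interface distance: 1.160 nm
E11 SASA (alpha mean over 1-133 ns): 1.103 nm^2
heme SASA (alpha mean over 1-133 ns): 1.861 nm^2
```

The counts recover the planted truth exactly; the distance means match the
generator's OU means (Fe–L1 0.213/0.209 nm, displacement 0.035 nm) and the
site-2 maximum sits at the planted 1.15 nm excursion up to the planted
0.02 nm noise. The other examples (`examples/01…04`) each exercise one
stage — gating detection, heme geometry and stacking, interface contacts,
and SASA burial — and print what the numbers mean.

A thin CLI wraps the same calls:

```sh
hemegate synth out/ --seed 1                 # generate a synthetic dataset
hemegate analyze config.yaml                 # full analysis from a YAML config
hemegate compare-structures low.pdb high.pdb --map-low low.yaml --map-high high.yaml
```

`analyze` writes TSV tables (swing records, Fe–L1 means, iron displacement,
interface maxima, RMSD fits, SASA averages) plus a `manifest.json` with all
parameters and input checksums; reruns are byte-identical.

Site maps are YAML (`species`, `chains: {A: alpha, …}`, `sites:` per
subunit class with `resid`/`resname`); the package ships maps only for its
synthetic system (`hemegate.synthetic_site_map`) — maps for real structures
must be curated against the deposited numbering, and the resolver fails
loudly on any residue-name mismatch.

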