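# Methods

This note records the models, conventions and design choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## Units and windows

All coordinates and distances are nm internally (GROMACS convention); the
swing-out threshold "7 Å" is stored as 0.7 nm. Stacking descriptors are
reported in Å, the unit the ring-geometry literature uses. Times are ns,
with a default frame spacing of 0.2 ns. Every statistic excludes frames
before a 1 ns equilibration cutoff, and window averages (Fe–L1, iron
displacement, SASA) default to 1–133 ns so replicates of unequal length
contribute comparably; when a trajectory is shorter than the window the
window is truncated with a warning.

## Swing-out events

An event is binary per chain-replicate trace: did the HisE7 Nε–Fe distance
ever strictly exceed the threshold in the analyzed window. Ties at exactly
0.7 nm do not count. Excursion-level detail (every maximal run above
threshold) is recorded alongside, but the count statistic is the binary
one — with two α chains and five replicates the maximum count is 10.

Two normalizations are applied and reported separately so either can be
undone from the output tables:

- event counts: raw × T_reference / T_treatment, where T_treatment sums
  each distinct replicate's length once (two chains of a replicate share
  one simulation);
- swing-out times (only traces with an event contribute; no event means no
  data point, not zero): t × (T_longest / T_replicate) × (T_reference /
  T_treatment).

The composite time normalization is one consistent reading of a
two-factor length correction (within-treatment to the longest replicate,
between-treatment to the reference total); because the algebra admits
alternatives, both factors appear as explicit columns in the outputs.

Return-to-down requires, after the first excursion ends, a contiguous run
at or below the down threshold lasting at least 5 ns (configurable). A
dwell requirement is needed because single-frame dips below threshold are
noise, not repositioning; 5 ns is ~25 frames at the default spacing, long
relative to the OU correlation time of the fluctuations and short relative
to replicate length.

## Heme geometry

Iron displacement is the point-to-point distance |Fe − C| where C is the
unweighted centroid of the four pyrrole nitrogens (all four atoms are
nitrogen, so mass weighting is a no-op), signed by which side of the
least-squares pyrrole plane holds the proximal-histidine reference atom
(positive = proximal side, the direction of T-state doming). The
perpendicular projection onto the plane normal is exposed alongside;
|Fe − C| is the default reported value because the quantity is defined as
a distance to the centroid, not a projection. Collinear pyrrole nitrogens
(second singular value of the centered coordinates ≈ 0) are a hard error.

Kabsch superposition uses the standard SVD construction with a determinant
correction so reflections are never applied. For the local interface RMSD
the superposition is computed on the analysis selection itself (the
backbone N/CA/O of the six interface residues), so the trace measures
internal loosening of the contact region rather than global tumbling.

Stacking classification: parallel-displaced if the interplanar angle is
< 30° and the centroid distance < 5.5 Å; T-shaped if > 60° and < 6.0 Å;
otherwise none. These cutoffs are package defaults chosen from the common
ranges in the π-stacking literature and are configurable; rings must be
planar to 0.3 Å RMS or the classification refuses to run.

No minimum-image correction is applied to distances by default:
intra-protein atom pairs in a ~10 nm box never span a periodic image. An
optional box-aware mode exists for the rare case where it matters.

## SASA

Shrake–Rupley with quasi-uniform Fibonacci-spiral test points (default
960 per atom; doubling changes results by < 0.5%), probe radius 0.14 nm,
Bondi van der Waals radii by element (Fe assigned 2.0 Å, a common
surface-table convention for the heme iron; any other table can be
passed, and the table name is recorded in output headers because absolute
SASA shifts with the radii set — comparisons are only meaningful
like-for-like). The occlusion context is protein + heme atoms only;
solvent and ions are excluded, so the value measures how open the pocket
is to a probe rather than instantaneous water contacts. Element inference
from atom names treats the heme dialect explicitly: FE is iron and the
pyrrole nitrogens NA/NB/NC/ND are nitrogen (sodium ions never reach the
radius table because ions are excluded from the context upstream).

## Interface sites

The four canonical α1–β2 contacts are defined as atom pairs with a species
applicability rule: the Thr(α1C6) OG → Arg(β2C6) CZ hydrogen bond requires
Thr at α1C6 and is refused (a structured applicability error) for maps
with Ala there, leaving three sites for trout-like species. Reports carry
both the internal letters A–D and the site 1/2/3 numbering, with the
bovine-only hydrogen bond labelled site 2′ because it shares the Arg β2C6
partner with site 2; keeping both labelings avoids silently conflating
the four atom pairs with the three numbered sites. Maxima are taken over
analyzed frames only (t ≥ 1 ns), consistent with the global cutoff.

## Statistics

Implemented from the standard formulas — ANOVA between/within
decomposition, Tukey–Kramer studentized-range pairwise comparisons,
pooled-variance (default) and Welch t statistics, closed-form OLS — with
scipy supplying only the reference distributions for p-values. Tukey HSD
is the specific "multiple comparisons" procedure because it is the common
default of interactive statistics packages for one-way ANOVA; the method
name is recorded in every result. The test suite checks the F = t²
two-group identity and agreement with scipy/statsmodels references to
1e-8 relative tolerance; the implementations themselves never call the
reference routines.

## Synthetic data: what it emulates and what it does not

The generator emits a chemically fake but geometrically exact minimal
tetramer (per chain: heme Fe + 4 pyrrole N, distal and proximal His, E11,
CE4, and the interface residues) through real file formats (PDB topology;
XTC trajectories written with 4-decimal precision, i.e. 1e-4 nm
quantization, so planted distances are recoverable well inside 1e-3 nm).

- Gating: a continuous-time two-state Markov path (down 0.45 nm, up
  0.90 nm) read out on the frame grid, plus stationary Ornstein–Uhlenbeck
  noise (sd 0.03 nm, correlation time 0.5 ns). OU rather than white noise
  so traces have the correlated frame-to-frame fluctuation of real MD
  distance series. The state means sit > 6.5 SD from the 0.7 nm threshold,
  making false crossings negligible (< 1e-10 per frame), so detected
  first-passage times equal planted switch times.
- Replicates: five by default, 135–150 ns (all covering the 1–133 ns
  window, as in the study design this emulates), deliberately unequal to
  exercise the length normalizations; 0.2 ns spacing.
- Heme geometry: Fe–L1 OU means 0.213 nm (α) / 0.209 nm (β) with sd
  0.004 nm, iron displacement 0.035 nm (α) / 0.030 nm (β) — values inside
  the 1.9–2.3 Å Fe–L1 range reported for heme proteins, with the α/β and
  displacement contrasts large enough to be resolved by the pooled n = 10
  means but small in absolute terms.
- Interface: the β2-side atoms of each contact track planted OU breathing
  series (means 0.55–0.60 nm, sd 0.02 nm); a smooth Gaussian excursion in
  one replicate takes site 2 to 1.15 nm, emulating a transient guanidinium
  swing toward solvent; the β2 interface backbone drifts slowly so the
  local RMSD has a nonzero OLS slope.
- E11 burial: a shell of occluder atoms around one E11 residue opens along
  a planted schedule. Occluders depart one by one (occluder j leaves when
  the open fraction passes j/n) rather than expanding uniformly, because
  removal can only increase the target's SASA — the response is exactly
  monotone in the schedule and spread over its whole range, instead of
  collapsing into the narrow radius band where a uniform shell starts to
  leak.

What passing tests therefore show: the measurement chain — file formats,
site resolution, geometry, detection, normalization, SASA, statistics —
recovers planted truth exactly or to stated tolerances. What they do not
show: anything about real protein dynamics. The synthetic tetramer has no
force-field validity, no coupling between observables, and noise that is
stationary by construction; agreement with it validates the analysis
code, not the science of any particular simulation.

## Problem sizes

The default synthetic system (5 replicates, ~700 frames each, ~320 atoms)
is sized so the full pipeline — including per-frame Shrake–Rupley on two
targets per α chain — completes in well under a minute, while still
giving 10 chain-replicate traces (the pooled n the statistics expect) and
6610-point averaging windows. The parameter-recovery study uses 500
seeded traces of 150 ns, enough for the binomial 95% CI on the swing-out
fraction to be ±0.02.

## Known limitations

- The trajectory container is fully in-memory; replicates of ~10⁵ frames
  × 10⁵ atoms would need a streaming path that does not exist here.
- SASA absolute values depend on the radii table; only like-for-like
  comparisons within one table are meaningful.
- detect_swing's return criterion uses a fixed dwell; a hidden-Markov
  segmentation of gating states is deliberately out of scope (the event
  definition is a fixed threshold).
- Site maps for real structures are user-curated; the package validates
  residue identity but cannot derive helical notation from sequence.
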