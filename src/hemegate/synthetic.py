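"""Synthetic structures and trajectories with planted ground truth.

The generator emits a chemically fake but geometrically exact minimal
hemoglobin tetramer: four chains (two alpha, two beta), each carrying a
heme (Fe + 4 pyrrole N), distal and proximal histidines, the E11 pocket
residue, the CE4 aromatic residue and the alpha1-beta2 interface residues
(C6, C7, FG4, G1, G4).  Per frame, the distal-His Ne atom is placed so
its distance to the Fe tracks a planted two-state (down ~4.5 A, up ~9 A)
gating series; interface atom pairs track planted breathing series with
optional large excursions; a shell of occluder atoms around one E11
residue opens along a planted schedule so its SASA follows the schedule.
Everything is written through real file formats (PDB topology, XTC
trajectories) plus a JSON ground-truth manifest, so every analysis stage
can be checked against known truth without any deposited data.

Gating noise is Ornstein-Uhlenbeck (mean-reverting, correlated) rather
than white, so traces resemble real MD distance fluctuations; default
amplitudes put the down state >8 SD below the 0.7 nm threshold, making
false threshold crossings negligible.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import DistanceTrace, window_mean
from .structure_io import (
    SiteEntry,
    SiteMap,
    StructureModel,
    Trajectory,
    read_structure,
    write_trajectory,
)

__all__ = [
    "GatingParams",
    "GatingTrace",
    "SwingPlan",
    "Site2Excursion",
    "SyntheticSystemSpec",
    "SyntheticReplicate",
    "SyntheticSystem",
    "generate_gating_trace",
    "generate_synthetic_system",
    "generate_e11_burial_series",
    "synthetic_site_map",
]

GATE_DIRECTION = np.array([0.6, 0.0, 0.8])  # unit vector for distal-His placement
SASA_SHELL_CLOSED_NM = 0.40
SASA_SHELL_OPEN_NM = 2.50


def _shell_radii(open_fraction: np.ndarray, n_occluders: int) -> np.ndarray:
    """(frames, occluders) shell radii for a burial schedule.

    Occluder j sits at the closed radius until the open fraction passes
    j / n, then retreats to the far radius.  Removing occluders can only
    raise the target's SASA, so the response is exactly monotone in the
    schedule and spread over its whole [0, 1] range (one step per occluder)
    rather than collapsing into the narrow radius band where a uniformly
    expanding shell starts to leak.
    """
    thresholds = np.arange(n_occluders) / n_occluders
    away = open_fraction[:, None] > thresholds[None, :]
    return np.where(away, SASA_SHELL_OPEN_NM, SASA_SHELL_CLOSED_NM)


@dataclass(frozen=True)
class GatingParams:
    """Two-state Markov gating model with OU observation noise.

    ``k_up``/``k_down`` are the down->up / up->down switching rates (1/ns);
    state means straddle the 0.7 nm event threshold (down 0.45 nm ~ 4.5 A,
    up 0.90 nm ~ 9 A, the ranges seen in gating distance traces); the OU
    noise (sd 0.03 nm, correlation time 0.5 ns) reproduces correlated
    frame-to-frame fluctuation at 0.2 ns sampling.
    """

    k_up: float
    k_down: float
    total_time: float  # ns
    mean_down: float = 0.45
    mean_up: float = 0.90
    ou_sd: float = 0.03
    ou_tau: float = 0.5
    frame_spacing: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_down < 0.7 < self.mean_up:
            raise ValueError("state means must straddle the 0.7 nm threshold")
        for name in ("k_up", "k_down"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("total_time", "ou_sd", "ou_tau", "frame_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GatingTrace:
    """A generated gating trace plus its planted truth."""

    trace: DistanceTrace
    states: np.ndarray  # 0 = down, 1 = up, per frame
    transition_times: list[tuple[float, int]]  # (continuous time ns, new state)
    first_up_time: float | None  # continuous time of the first down->up switch


def _ou_series(n: int, dt: float, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary OU samples at spacing dt (exact discretization)."""
    a = np.exp(-dt / tau)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), size=max(n - 1, 0))
    for k in range(1, n):
        x[k] = a * x[k - 1] + innov[k - 1]
    return x


def _sample_transitions(
    k_up: float, k_down: float, total_time: float, rng: np.random.Generator
) -> list[tuple[float, int]]:
    t, state = 0.0, 0
    out: list[tuple[float, int]] = []
    while True:
        rate = k_up if state == 0 else k_down
        if rate <= 0.0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= total_time:
            break
        state = 1 - state
        out.append((t, state))
    return out


def _states_at(times: np.ndarray, transitions: Sequence[tuple[float, int]]) -> np.ndarray:
    states = np.zeros(len(times), dtype=int)
    state = 0
    prev = 0.0
    for t_switch, new_state in list(transitions) + [(np.inf, -1)]:
        mask = (times >= prev) & (times < t_switch)
        states[mask] = state
        if new_state < 0:
            break
        state, prev = new_state, t_switch
    return states


def _frame_times(total_time: float, spacing: float) -> np.ndarray:
    n = int(round(total_time / spacing)) + 1
    return np.arange(n) * spacing


def generate_gating_trace(params: GatingParams, *, label: str = "gating") -> GatingTrace:
    """Sample one two-state Markov gating trace with OU noise.

    The continuous-time Markov path is sampled first, then read out on the
    frame grid; the observed distance is the state mean plus stationary OU
    noise.  Reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    transitions = _sample_transitions(params.k_up, params.k_down, params.total_time, rng)
    times = _frame_times(params.total_time, params.frame_spacing)
    states = _states_at(times, transitions)
    noise = _ou_series(len(times), params.frame_spacing, params.ou_sd, params.ou_tau, rng)
    means = np.where(states == 1, params.mean_up, params.mean_down)
    values = np.clip(means + noise, 0.0, None)
    first_up = next((t for t, s in transitions if s == 1), None)
    return GatingTrace(
        trace=DistanceTrace(label=label, times=times, values=values),
        states=states,
        transition_times=transitions,
        first_up_time=first_up,
    )


@dataclass(frozen=True)
class SwingPlan:
    """One planted swing-out: which replicate/chain, when, and whether it returns."""

    replicate_index: int
    chain_id: str
    t_up_ns: float
    t_return_ns: float | None = None


@dataclass(frozen=True)
class Site2Excursion:
    """A planted large excursion of interface site B ("site 2")."""

    replicate_index: int = 1
    t_center_ns: float = 70.0
    peak_nm: float = 1.15
    width_ns: float = 2.0


@dataclass
class SyntheticSystemSpec:
    """Study conditions for a generated replicate set.

    Defaults follow the conditions the analysis is built for: 5 replicates
    of unequal length (all covering the 1-133 ns averaging window) at
    0.2 ns frame spacing, 2 alpha + 2 beta chains, three of the ten
    alpha-chain traces swinging out with one returning down, one interface
    site-2 excursion above 1 nm, and a monotone E11 burial schedule on one
    chain.
    """

    species: str = "synthetic-bovine-like"
    n_replicates: int = 5
    replicate_lengths_ns: tuple[float, ...] = (150.0, 140.0, 135.0, 145.0, 138.0)
    frame_spacing_ns: float = 0.2
    swing_plan: tuple[SwingPlan, ...] = (
        SwingPlan(0, "A", 20.0, 80.0),
        SwingPlan(2, "A", 60.0, None),
        SwingPlan(4, "B", 35.0, None),
    )
    site2_excursion: Site2Excursion | None = Site2Excursion()
    gating_mean_down: float = 0.45
    gating_mean_up: float = 0.90
    gating_sd: float = 0.03
    gating_tau: float = 0.5
    fe_l1_mean_alpha: float = 0.213
    fe_l1_mean_beta: float = 0.209
    fe_l1_sd: float = 0.004
    fe_l1_tau: float = 1.0
    iron_disp_mean_alpha: float = 0.035
    iron_disp_mean_beta: float = 0.030
    iron_disp_sd: float = 0.002
    interface_means_nm: tuple[float, float, float] = (0.55, 0.55, 0.60)  # sites A, B, C
    interface_sd: float = 0.02
    interface_tau: float = 2.0
    backbone_drift_rate: float = 0.0002  # nm/ns, beta2 interface backbone
    e11_burial_chain: str = "A"
    n_occluders: int = 60

    def __post_init__(self) -> None:
        if len(self.replicate_lengths_ns) != self.n_replicates:
            raise ValueError("replicate_lengths_ns must match n_replicates")
        for plan in self.swing_plan:
            if not 0 <= plan.replicate_index < self.n_replicates:
                raise ValueError("swing plan references a missing replicate")
            if plan.t_up_ns >= self.replicate_lengths_ns[plan.replicate_index]:
                raise ValueError("planted swing time beyond replicate length")


@dataclass
class SyntheticReplicate:
    replicate_id: str
    length_ns: float
    times: np.ndarray
    trajectory_path: Path
    gate_series: dict[str, np.ndarray]  # chain -> planted HisE7 Ne - Fe distance (nm)
    gate_states: dict[str, np.ndarray]
    swing_truth: dict[str, dict]  # chain -> {swung_out, t_up, t_return}
    fe_l1_series: dict[str, np.ndarray]
    iron_disp_series: dict[str, np.ndarray]
    interface_series: dict[str, np.ndarray]  # site id -> planted distance (nm)
    open_schedule: np.ndarray  # E11 shell open fraction per frame


@dataclass
class SyntheticSystem:
    spec: SyntheticSystemSpec
    model: StructureModel
    site_map: SiteMap
    topology_path: Path
    site_map_path: Path
    manifest_path: Path
    replicates: list[SyntheticReplicate]

    @property
    def alpha1_chain(self) -> str:
        return "A"

    @property
    def beta2_chain(self) -> str:
        return "D"


# ---------------------------------------------------------------------------
# topology construction

_CHAIN_ORIGINS = {"A": (0.0, 0.0, 0.0), "B": (8.0, 0.0, 0.0),
                  "C": (0.0, 8.0, 0.0), "D": (8.0, 8.0, 0.0)}
_CHAIN_CLASSES = {"A": "alpha", "B": "alpha", "C": "beta", "D": "beta"}

# resids of the helical sites within every synthetic chain
_RESIDS = {"F8": 1, "E7": 2, "E11": 3, "CE4": 4, "C6": 5, "C7": 6,
           "FG4": 7, "G1": 8, "G4": 9, "E10": 10, "E3": 11}
_HEME_RESID = 100
_OCC_RESID = 90


def _species_residues(species: str) -> dict[str, str]:
    bovine_like = "bovine" in species
    return {
        "F8": "HIS", "E7": "HIS",
        "E11": "VAL" if bovine_like else "ILE",
        "CE4": "PHE" if bovine_like else "TRP",
        "C6_alpha": "THR" if bovine_like else "ALA",
        "C6_beta": "ARG",
        "C7": "TYR", "FG4": "ARG", "G1": "ASP", "G4": "ASN",
        "E10": "LYS" if bovine_like else "THR", "E3": "GLY",
    }


def synthetic_site_map(species: str = "synthetic-bovine-like") -> SiteMap:
    """Site map for the generated tetramer (ships with the package)."""
    res = _species_residues(species)
    entries: dict[tuple[str, str], SiteEntry] = {}
    for subunit in ("alpha", "beta"):
        for site, resid in _RESIDS.items():
            if site == "C6":
                resname = res["C6_alpha"] if subunit == "alpha" else res["C6_beta"]
            else:
                resname = res[site]
            entries[(subunit, site)] = SiteEntry(resid, resname)
    return SiteMap(species=species, chain_classes=dict(_CHAIN_CLASSES), entries=entries)


@dataclass
class _AtomSpec:
    chain: str
    resid: int
    resname: str
    name: str
    base: np.ndarray  # nm
    hetatm: bool = False


def _fib_directions(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _build_atoms(spec: SyntheticSystemSpec) -> list[_AtomSpec]:
    res = _species_residues(spec.species)
    atoms: list[_AtomSpec] = []

    def add(chain, resid, resname, name, pos, hetatm=False):
        atoms.append(_AtomSpec(chain, resid, resname, name, np.asarray(pos, dtype=float), hetatm))

    for chain, origin in _CHAIN_ORIGINS.items():
        o = np.asarray(origin)
        h = o + np.array([2.0, 2.0, 2.0])  # heme center (pyrrole-N centroid)
        # proximal His F8: Ne2 placed per frame, backbone static
        add(chain, _RESIDS["F8"], "HIS", "N", h + [0.30, 0.00, 0.50])
        add(chain, _RESIDS["F8"], "HIS", "CA", h + [0.40, 0.00, 0.55])
        add(chain, _RESIDS["F8"], "HIS", "O", h + [0.50, 0.00, 0.50])
        add(chain, _RESIDS["F8"], "HIS", "NE2", h + [0.0, 0.0, 0.25])  # mover
        # distal His E7: Ne2 + imidazole ring follow the gating series
        add(chain, _RESIDS["E7"], "HIS", "N", h + [-0.80, 0.00, 0.30])
        add(chain, _RESIDS["E7"], "HIS", "CA", h + [-0.90, 0.00, 0.35])
        add(chain, _RESIDS["E7"], "HIS", "O", h + [-1.00, 0.00, 0.30])
        for name, off in (("CG", [0.22, 0.00, 0.00]), ("ND1", [0.14, 0.18, 0.00]),
                          ("CD2", [0.12, -0.20, 0.00]), ("CE1", [0.00, 0.15, 0.00]),
                          ("NE2", [0.0, 0.0, 0.0])):
            add(chain, _RESIDS["E7"], "HIS", name, h + [0.3, 0.0, 0.4] + np.asarray(off))  # movers
        # E11 pocket residue
        e = o + np.array([2.0, 5.0, 2.0])
        e11 = res["E11"]
        add(chain, _RESIDS["E11"], e11, "N", e + [0.00, 0.10, 0.00])
        add(chain, _RESIDS["E11"], e11, "CA", e + [0.05, 0.00, 0.00])
        add(chain, _RESIDS["E11"], e11, "O", e + [-0.10, 0.05, 0.00])
        add(chain, _RESIDS["E11"], e11, "CB", e)
        add(chain, _RESIDS["E11"], e11, "CG1", e + [0.10, 0.00, 0.05])
        add(chain, _RESIDS["E11"], e11, "CG2", e + [0.00, -0.10, 0.05])
        # CE4 aromatic residue: static planar six-ring
        c = o + np.array([4.5, 2.0, 2.0])
        ce4 = res["CE4"]
        add(chain, _RESIDS["CE4"], ce4, "N", c + [-0.30, 0.00, 0.00])
        add(chain, _RESIDS["CE4"], ce4, "CA", c + [-0.25, 0.10, 0.00])
        add(chain, _RESIDS["CE4"], ce4, "O", c + [-0.35, 0.10, 0.00])
        for j, name in enumerate(("CG", "CD1", "CD2", "CE1", "CE2", "CZ")):
            ang = j * np.pi / 3.0
            add(chain, _RESIDS["CE4"], ce4, name, c + [0.14 * np.cos(ang), 0.14 * np.sin(ang), 0.0])
        # interface residues
        c6name = res["C6_alpha"] if _CHAIN_CLASSES[chain] == "alpha" else res["C6_beta"]
        p = o + np.array([5.0, 3.0, 2.0])
        add(chain, _RESIDS["C6"], c6name, "N", p + [0.00, 0.10, 0.00])
        add(chain, _RESIDS["C6"], c6name, "CA", p + [0.05, 0.00, 0.00])
        add(chain, _RESIDS["C6"], c6name, "O", p + [-0.10, 0.00, 0.00])
        add(chain, _RESIDS["C6"], c6name, "CB", p + [0.10, 0.05, 0.00])
        if c6name == "THR":
            add(chain, _RESIDS["C6"], c6name, "OG", p + [0.10, 0.10, 0.00])
        if c6name == "ARG":
            add(chain, _RESIDS["C6"], c6name, "CD", p + [0.20, 0.05, 0.00])
            add(chain, _RESIDS["C6"], c6name, "CZ", p + [0.30, 0.05, 0.00])  # mover (chain D)
        p = o + np.array([5.0, 3.6, 2.0])
        add(chain, _RESIDS["C7"], "TYR", "N", p + [0.00, 0.10, 0.00])
        add(chain, _RESIDS["C7"], "TYR", "CA", p + [0.05, 0.00, 0.00])
        add(chain, _RESIDS["C7"], "TYR", "O", p + [-0.10, 0.00, 0.00])
        add(chain, _RESIDS["C7"], "TYR", "CB", p + [0.10, 0.05, 0.00])
        add(chain, _RESIDS["C7"], "TYR", "CZ", p + [0.15, 0.00, 0.00])
        p = o + np.array([5.0, 4.2, 2.0])
        add(chain, _RESIDS["FG4"], "ARG", "N", p + [0.00, 0.10, 0.00])
        add(chain, _RESIDS["FG4"], "ARG", "CA", p + [0.05, 0.00, 0.00])
        add(chain, _RESIDS["FG4"], "ARG", "O", p + [-0.10, 0.00, 0.00])
        add(chain, _RESIDS["FG4"], "ARG", "CB", p + [0.10, 0.05, 0.00])
        add(chain, _RESIDS["FG4"], "ARG", "CD", p + [0.12, 0.00, 0.00])
        add(chain, _RESIDS["FG4"], "ARG", "CZ", p + [0.25, 0.00, 0.00])
        p = o + np.array([5.0, 4.8, 2.0])
        add(chain, _RESIDS["G1"], "ASP", "N", p + [0.00, 0.10, 0.00])
        add(chain, _RESIDS["G1"], "ASP", "CA", p + [0.05, 0.00, 0.00])
        add(chain, _RESIDS["G1"], "ASP", "O", p + [-0.10, 0.00, 0.00])
        add(chain, _RESIDS["G1"], "ASP", "CB", p + [0.10, 0.05, 0.00])
        add(chain, _RESIDS["G1"], "ASP", "CG", p + [0.12, 0.00, 0.00])
        p = o + np.array([5.0, 5.4, 2.0])
        add(chain, _RESIDS["G4"], "ASN", "N", p + [0.00, 0.10, 0.00])
        add(chain, _RESIDS["G4"], "ASN", "CA", p + [0.05, 0.00, 0.00])
        add(chain, _RESIDS["G4"], "ASN", "O", p + [-0.10, 0.00, 0.00])
        add(chain, _RESIDS["G4"], "ASN", "CB", p + [0.10, 0.05, 0.00])
        add(chain, _RESIDS["G4"], "ASN", "ND2", p + [0.12, 0.00, 0.00])  # mover (chain D)
        p = o + np.array([3.0, 5.0, 2.0])
        for name, off in (("N", [0.0, 0.1, 0.0]), ("CA", [0.05, 0.0, 0.0]), ("O", [-0.1, 0.0, 0.0])):
            add(chain, _RESIDS["E10"], res["E10"], name, p + np.asarray(off))
        p = o + np.array([1.0, 5.0, 2.0])
        for name, off in (("N", [0.0, 0.1, 0.0]), ("CA", [0.05, 0.0, 0.0]), ("O", [-0.1, 0.0, 0.0])):
            add(chain, _RESIDS["E3"], res["E3"], name, p + np.asarray(off))
        # heme: Fe is a mover, pyrrole nitrogens static in the z = h_z plane
        add(chain, _HEME_RESID, "HEM", "FE", h + [0.0, 0.0, 0.03], hetatm=True)
        add(chain, _HEME_RESID, "HEM", "NA", h + [0.20, 0.00, 0.00], hetatm=True)
        add(chain, _HEME_RESID, "HEM", "NB", h + [0.00, 0.20, 0.00], hetatm=True)
        add(chain, _HEME_RESID, "HEM", "NC", h + [-0.20, 0.00, 0.00], hetatm=True)
        add(chain, _HEME_RESID, "HEM", "ND", h + [0.00, -0.20, 0.00], hetatm=True)
        # occluder shell around the burial chain's E11
        if chain == spec.e11_burial_chain:
            dirs = _fib_directions(spec.n_occluders)
            for j in range(spec.n_occluders):
                add(chain, _OCC_RESID, "OCC", f"C{j + 1}",
                    e + SASA_SHELL_CLOSED_NM * dirs[j], hetatm=True)  # movers
    return atoms


def _write_pdb(atoms: list[_AtomSpec], path: Path) -> None:
    lines = []
    serial = 0
    for a in atoms:
        serial += 1
        record = "HETATM" if a.hetatm else "ATOM"
        name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
        x, y, z = a.base * 10.0  # nm -> Angstrom
        elem = "FE" if a.name == "FE" else a.name.lstrip("0123456789")[0]
        lines.append(
            f"{record:<6}{serial:>5} {name:<4} {a.resname:<3} {a.chain}{a.resid:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem:>2}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _gauss_bump(times: np.ndarray, t0: float, height: float, width: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((times - t0) / width) ** 2)


def generate_synthetic_system(
    out_dir: str | Path,
    spec: SyntheticSystemSpec = SyntheticSystemSpec(),
    seed: int = 0,
) -> SyntheticSystem:
    """Write a full synthetic replicate set and return it with planted truth.

    Emits ``topology.pdb``, ``site_map.yaml``, one XTC trajectory per
    replicate and ``ground_truth.json``.  The planted distance series are
    exactly recoverable from the emitted coordinates by the geometry module
    (to trajectory-format precision, <= 1e-3 nm).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    atoms = _build_atoms(spec)
    topo_path = out_dir / "topology.pdb"
    _write_pdb(atoms, topo_path)
    site_map = synthetic_site_map(spec.species)
    map_path = out_dir / "site_map.yaml"
    site_map.to_yaml(map_path)
    model = read_structure(topo_path, chain_classes=_CHAIN_CLASSES)

    index = {(a.chain, a.resid, a.name): i for i, a in enumerate(atoms)}
    base = np.array([a.base for a in atoms])
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(spec.n_replicates)

    swing_by_rep: dict[int, dict[str, SwingPlan]] = {}
    for plan in spec.swing_plan:
        swing_by_rep.setdefault(plan.replicate_index, {})[plan.chain_id] = plan

    replicates: list[SyntheticReplicate] = []
    for r in range(spec.n_replicates):
        length = spec.replicate_lengths_ns[r]
        times = _frame_times(length, spec.frame_spacing_ns)
        n_frames = len(times)
        rng = np.random.default_rng(rep_seeds[r])
        coords = np.tile(base, (n_frames, 1, 1))

        gate_series: dict[str, np.ndarray] = {}
        gate_states: dict[str, np.ndarray] = {}
        swing_truth: dict[str, dict] = {}
        fe_l1_series: dict[str, np.ndarray] = {}
        disp_series: dict[str, np.ndarray] = {}

        for chain in _CHAIN_ORIGINS:
            is_alpha = _CHAIN_CLASSES[chain] == "alpha"
            h = np.asarray(_CHAIN_ORIGINS[chain]) + np.array([2.0, 2.0, 2.0])
            disp_mean = spec.iron_disp_mean_alpha if is_alpha else spec.iron_disp_mean_beta
            fe_l1_mean = spec.fe_l1_mean_alpha if is_alpha else spec.fe_l1_mean_beta
            disp = disp_mean + _ou_series(n_frames, spec.frame_spacing_ns,
                                          spec.iron_disp_sd, spec.fe_l1_tau, rng)
            fe_l1 = fe_l1_mean + _ou_series(n_frames, spec.frame_spacing_ns,
                                            spec.fe_l1_sd, spec.fe_l1_tau, rng)
            plan = swing_by_rep.get(r, {}).get(chain)
            transitions: list[tuple[float, int]] = []
            if plan is not None:
                transitions.append((plan.t_up_ns, 1))
                if plan.t_return_ns is not None:
                    transitions.append((plan.t_return_ns, 0))
            states = _states_at(times, transitions)
            noise = _ou_series(n_frames, spec.frame_spacing_ns, spec.gating_sd,
                               spec.gating_tau, rng)
            gate = np.where(states == 1, spec.gating_mean_up, spec.gating_mean_down) + noise
            gate = np.clip(gate, 0.05, None)

            fe_pos = h + np.outer(disp, [0.0, 0.0, 1.0])
            coords[:, index[(chain, _HEME_RESID, "FE")], :] = fe_pos
            coords[:, index[(chain, _RESIDS["F8"], "NE2")], :] = (
                h + np.outer(disp + fe_l1, [0.0, 0.0, 1.0])
            )
            ne2 = fe_pos + np.outer(gate, GATE_DIRECTION)
            for name, off in (("NE2", [0.0, 0.0, 0.0]), ("CG", [0.22, 0.0, 0.0]),
                              ("ND1", [0.14, 0.18, 0.0]), ("CD2", [0.12, -0.2, 0.0]),
                              ("CE1", [0.0, 0.15, 0.0])):
                coords[:, index[(chain, _RESIDS["E7"], name)], :] = ne2 + np.asarray(off)

            gate_series[chain] = gate
            gate_states[chain] = states
            fe_l1_series[chain] = fe_l1
            disp_series[chain] = disp
            swing_truth[chain] = {
                "swung_out": plan is not None,
                "t_up_ns": plan.t_up_ns if plan else None,
                "t_return_ns": plan.t_return_ns if plan else None,
            }

        # interface breathing: move beta2 (chain D) side atoms relative to
        # the static alpha1 (chain A) side atoms
        site_means = dict(zip(("A", "B", "C"), spec.interface_means_nm))
        d1 = site_means["A"] + _ou_series(n_frames, spec.frame_spacing_ns,
                                          spec.interface_sd, spec.interface_tau, rng)
        d2 = site_means["B"] + _ou_series(n_frames, spec.frame_spacing_ns,
                                          spec.interface_sd, spec.interface_tau, rng)
        d3 = site_means["C"] + _ou_series(n_frames, spec.frame_spacing_ns,
                                          spec.interface_sd, spec.interface_tau, rng)
        exc = spec.site2_excursion
        if exc is not None and exc.replicate_index == r:
            d2 = d2 + _gauss_bump(times, exc.t_center_ns,
                                  exc.peak_nm - site_means["B"], exc.width_ns)
        d1, d2, d3 = (np.clip(d, 0.05, None) for d in (d1, d2, d3))

        a_g1_cg = base[index[("A", _RESIDS["G1"], "CG")]]
        a_c7_cz = base[index[("A", _RESIDS["C7"], "CZ")]]
        a_fg4_cd = base[index[("A", _RESIDS["FG4"], "CD")]]
        e1, e2, e3 = np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
        cz_d = a_c7_cz + np.outer(d2, e2)
        coords[:, index[("D", _RESIDS["G4"], "ND2")], :] = a_g1_cg + np.outer(d1, e1)
        coords[:, index[("D", _RESIDS["C6"], "CZ")], :] = cz_d
        coords[:, index[("D", _RESIDS["C6"], "CB")], :] = a_fg4_cd + np.outer(d3, e3)
        interface_series = {"A": d1, "B": d2, "C": d3}
        if site_map.chain_classes and _species_residues(spec.species)["C6_alpha"] == "THR":
            a_c6_og = base[index[("A", _RESIDS["C6"], "OG")]]
            interface_series["D"] = np.linalg.norm(cz_d - a_c6_og, axis=1)

        # slow drift of the beta2 interface backbone (local RMSD trend)
        drift = np.outer(spec.backbone_drift_rate * times, [0.0, 0.0, 1.0])
        for site in ("C6", "G4"):
            for name in ("N", "CA", "O"):
                i = index[("D", _RESIDS[site], name)]
                coords[:, i, :] = base[i] + drift

        # E11 occluder shell opens along a linear schedule
        open_schedule = times / times[-1]
        if spec.e11_burial_chain:
            chain = spec.e11_burial_chain
            e_center = np.asarray(_CHAIN_ORIGINS[chain]) + np.array([2.0, 5.0, 2.0])
            dirs = _fib_directions(spec.n_occluders)
            radii_jt = _shell_radii(open_schedule, spec.n_occluders)
            for j in range(spec.n_occluders):
                i = index[(chain, _OCC_RESID, f"C{j + 1}")]
                coords[:, i, :] = e_center + np.outer(radii_jt[:, j], dirs[j])

        traj_path = out_dir / f"rep{r + 1}.xtc"
        write_trajectory(model, coords, traj_path, frame_spacing=spec.frame_spacing_ns)
        replicates.append(SyntheticReplicate(
            replicate_id=f"rep{r + 1}",
            length_ns=float(times[-1]),
            times=times,
            trajectory_path=traj_path,
            gate_series=gate_series,
            gate_states=gate_states,
            swing_truth=swing_truth,
            fe_l1_series=fe_l1_series,
            iron_disp_series=disp_series,
            interface_series=interface_series,
            open_schedule=open_schedule,
        ))

    manifest_path = out_dir / "ground_truth.json"
    _write_manifest(manifest_path, spec, seed, replicates)
    return SyntheticSystem(
        spec=spec,
        model=model,
        site_map=site_map,
        topology_path=topo_path,
        site_map_path=map_path,
        manifest_path=manifest_path,
        replicates=replicates,
    )


def _write_manifest(path: Path, spec: SyntheticSystemSpec, seed: int,
                    replicates: list[SyntheticReplicate]) -> None:
    window = (1.0, 133.0)
    reps = []
    for rep in replicates:
        mask = (rep.times >= window[0]) & (rep.times <= window[1])
        reps.append({
            "replicate_id": rep.replicate_id,
            "length_ns": rep.length_ns,
            "n_frames": len(rep.times),
            "trajectory": rep.trajectory_path.name,
            "swing": rep.swing_truth,
            "interface_max_nm": {k: float(v[mask].max()) for k, v in rep.interface_series.items()},
            "fe_l1_window_mean_nm": {k: float(v[mask].mean()) for k, v in rep.fe_l1_series.items()},
            "iron_disp_window_mean_nm": {k: float(v[mask].mean())
                                         for k, v in rep.iron_disp_series.items()},
        })
    planted_swings = sorted(
        (p.replicate_index, p.chain_id, p.t_up_ns, p.t_return_ns) for p in spec.swing_plan
    )
    manifest = {
        "seed": seed,
        "species": spec.species,
        "frame_spacing_ns": spec.frame_spacing_ns,
        "averaging_window_ns": list(window),
        "chains": _CHAIN_CLASSES,
        "planted": {
            "n_swing_events": len(spec.swing_plan),
            "n_returns": sum(1 for p in spec.swing_plan if p.t_return_ns is not None),
            "swings": [list(s) for s in planted_swings],
            "site2_excursion": asdict(spec.site2_excursion) if spec.site2_excursion else None,
        },
        "replicates": reps,
    }
    path.write_text(json.dumps(manifest, indent=1))


def generate_e11_burial_series(
    open_fraction: Sequence[float],
    *,
    seed: int = 0,
    n_occluders: int = 60,
    frame_spacing: float = 0.2,
) -> tuple[StructureModel, Trajectory, SiteMap]:
    """Mini system exercising pocket-burial SASA logic.

    One E11-like residue surrounded by a shell of occluder atoms whose
    radius follows ``open_fraction`` (0 = fully buried, 1 = fully open), so
    the residue's SASA varies monotonically with the planted schedule.
    Returns an in-memory model, trajectory and matching site map.
    """
    sched = np.asarray(open_fraction, dtype=float)
    if sched.ndim != 1 or len(sched) == 0 or np.any((sched < 0) | (sched > 1)):
        raise ValueError("open_fraction must be a 1-D schedule in [0, 1]")
    e = np.zeros(3)
    atoms: list[_AtomSpec] = []
    for name, off in (("N", [0.0, 0.1, 0.0]), ("CA", [0.05, 0.0, 0.0]),
                      ("O", [-0.1, 0.05, 0.0]), ("CB", [0.0, 0.0, 0.0]),
                      ("CG1", [0.1, 0.0, 0.05]), ("CG2", [0.0, -0.1, 0.05])):
        atoms.append(_AtomSpec("A", _RESIDS["E11"], "VAL", name, e + np.asarray(off)))
    dirs = _fib_directions(n_occluders)
    for j in range(n_occluders):
        atoms.append(_AtomSpec("A", _OCC_RESID, "OCC", f"C{j + 1}",
                               e + SASA_SHELL_CLOSED_NM * dirs[j], hetatm=True))
    base = np.array([a.base for a in atoms])
    model = StructureModel(
        chain_ids=np.array([a.chain for a in atoms]),
        residue_indices=np.array([a.resid for a in atoms]),
        residue_names=np.array([a.resname for a in atoms]),
        atom_names=np.array([a.name for a in atoms]),
        positions=base.copy(),
        chain_classes={"A": "alpha"},
    )
    n_frames = len(sched)
    coords = np.tile(base, (n_frames, 1, 1))
    radii_jt = _shell_radii(sched, n_occluders)
    for j in range(n_occluders):
        coords[:, 6 + j, :] = e + np.outer(radii_jt[:, j], dirs[j])
    traj = Trajectory(times=np.arange(n_frames) * frame_spacing, coordinates=coords,
                      frame_spacing=frame_spacing)
    site_map = SiteMap(
        species="synthetic-burial",
        chain_classes={"A": "alpha"},
        entries={("alpha", "E11"): SiteEntry(_RESIDS["E11"], "VAL")},
    )
    return model, traj, site_map
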