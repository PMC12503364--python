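"""Shrake-Rupley solvent-accessible surface area.

Per-atom SASA from quasi-uniform (Fibonacci-spiral) test points on each
atom's solvent-expanded sphere: a point is accessible if no other atom's
expanded sphere covers it; the atom's area is the accessible point fraction
times 4 pi (r_vdw + probe)^2.  Targets (a residue, the heme moiety) are
evaluated in the context of the protein + heme atoms only — solvent and
ions are excluded, so the value measures how open the pocket is to a probe,
not instantaneous water contacts.

Units: nm and nm^2 throughout.  Default probe radius 0.14 nm (water);
default radii are the Bondi van der Waals set (a GROMACS-style table can be
passed instead — absolute values shift with the table, so comparisons must
be like-for-like and the table name is recorded in output headers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import window_mean
from .structure_io import StructureModel, SiteMap, Trajectory, resolve_site

__all__ = [
    "SASAParams",
    "SASATrace",
    "BONDI_RADII_NM",
    "atom_radii",
    "sphere_points",
    "shrake_rupley",
    "residue_sasa_trace",
    "heme_sasa_trace",
    "mean_sasa",
]

#: Bondi van der Waals radii (nm) by element; Fe uses the 2.0 A convention
#: common in surface-area tables (Bondi did not tabulate transition metals).
BONDI_RADII_NM: dict[str, float] = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "FE": 0.200,
}

_ELEMENT_LETTERS = ("H", "C", "N", "O", "S", "P")


@dataclass(frozen=True)
class SASAParams:
    probe_radius: float = 0.14  # nm
    n_sphere_points: int = 960
    radii_set: str = "bondi"

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 24:
            raise ValueError("n_sphere_points must be >= 24")


@dataclass
class SASATrace:
    """Per-frame SASA (nm^2) of one target group."""

    target_label: str
    times: np.ndarray  # ns
    values: np.ndarray  # nm^2
    params: SASAParams = SASAParams()
    equilibration_cutoff: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if np.any(self.values < -1e-12):
            raise ValueError("SASA values must be non-negative")


def element_of(atom_name: str) -> str:
    """Infer the element from an atom name (CHARMM/PDB heme dialects included).

    ``FE`` is iron; otherwise the first letter decides, so the heme pyrrole
    nitrogens ``NA``/``NB``/``NC``/``ND`` are nitrogen (sodium ions are
    excluded from analysis contexts upstream and never reach here).
    """
    name = atom_name.strip().upper()
    if not name:
        raise ValueError("empty atom name")
    if name.startswith("FE"):
        return "FE"
    head = name.lstrip("0123456789")
    if head and head[0] in _ELEMENT_LETTERS:
        return head[0]
    raise ValueError(f"cannot infer element for atom name {atom_name!r}")


def atom_radii(
    atom_names: Sequence[str],
    table: Mapping[str, float] = BONDI_RADII_NM,
) -> np.ndarray:
    """Van der Waals radius (nm) per atom, keyed by inferred element."""
    radii = np.empty(len(atom_names))
    for i, name in enumerate(atom_names):
        elem = element_of(str(name))
        if elem not in table:
            raise ValueError(f"no van der Waals radius for element {elem} (atom {name})")
        radii[i] = table[elem]
    return radii


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere directions (Fibonacci spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    positions: np.ndarray,
    radii: np.ndarray,
    target_indices: Sequence[int],
    context_indices: Sequence[int],
    params: SASAParams = SASAParams(),
) -> np.ndarray:
    """Per-target-atom SASA (nm^2) of one frame.

    ``context_indices`` are the occluding atoms; target atoms occlude each
    other as well, whether or not they are listed in the context.
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    target = np.asarray(target_indices, dtype=int)
    context = np.asarray(context_indices, dtype=int)
    occluders = np.union1d(target, context)
    occ_pos = positions[occluders]
    occ_rad = radii[occluders] + params.probe_radius
    tree = cKDTree(occ_pos)
    unit = sphere_points(params.n_sphere_points)
    max_rad = float(occ_rad.max()) if len(occ_rad) else 0.0

    out = np.empty(len(target))
    # map occluder array position back to global index to drop the atom itself
    occ_lookup = {int(g): j for j, g in enumerate(occluders)}
    for t, gi in enumerate(target):
        big_r = radii[gi] + params.probe_radius
        center = positions[gi]
        neigh = tree.query_ball_point(center, big_r + max_rad)
        neigh = [j for j in neigh if j != occ_lookup[int(gi)]]
        area = 4.0 * np.pi * big_r**2
        if not neigh:
            out[t] = area
            continue
        pts = center + big_r * unit  # (P, 3)
        npos = occ_pos[neigh]  # (M, 3)
        nrad = occ_rad[neigh]
        d2 = np.sum((pts[:, None, :] - npos[None, :, :]) ** 2, axis=2)
        covered = np.any(d2 < nrad[None, :] ** 2, axis=1)
        out[t] = area * float(np.count_nonzero(~covered)) / params.n_sphere_points
    return out


def _group_sasa_trace(
    traj: Trajectory,
    model: StructureModel,
    target_indices: np.ndarray,
    label: str,
    params: SASAParams,
    radii_table: Mapping[str, float],
    equilibration_cutoff: float,
) -> SASATrace:
    context = model.analysis_context_indices()
    radii = np.zeros(model.n_atoms)
    relevant = np.union1d(context, target_indices)
    radii[relevant] = atom_radii(model.atom_names[relevant], radii_table)
    values = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        values[k] = shrake_rupley(traj.coordinates[k], radii, target_indices, context, params).sum()
    return SASATrace(
        target_label=label,
        times=traj.times.copy(),
        values=values,
        params=params,
        equilibration_cutoff=equilibration_cutoff,
    )


def residue_sasa_trace(
    traj: Trajectory,
    model: StructureModel,
    site_map: SiteMap,
    subunit_class: str,
    chain_id: str,
    site: str = "E11",
    params: SASAParams = SASAParams(),
    *,
    radii_table: Mapping[str, float] = BONDI_RADII_NM,
    equilibration_cutoff: float = 1.0,
) -> SASATrace:
    """Per-frame SASA of one mapped residue (default the E11 pocket residue)."""
    entry = site_map.entry(subunit_class, site)
    # validates residue identity en passant
    resolve_site(model, site_map, subunit_class, site, "CA", chain_id=chain_id)
    target = model.residue_atom_indices(chain_id, entry.residue_index)
    label = f"{chain_id}:{site}:{model.residue_name(chain_id, entry.residue_index)}"
    return _group_sasa_trace(traj, model, target, label, params, radii_table, equilibration_cutoff)


def heme_sasa_trace(
    traj: Trajectory,
    model: StructureModel,
    chain_id: str,
    params: SASAParams = SASAParams(),
    *,
    radii_table: Mapping[str, float] = BONDI_RADII_NM,
    equilibration_cutoff: float = 1.0,
) -> SASATrace:
    """Per-frame SASA of the heme moiety (all atoms of the chain's heme residue)."""
    heme = model.heme_for_chain(chain_id)
    target = model.residue_atom_indices(heme.chain_id, heme.residue_index)
    return _group_sasa_trace(
        traj, model, target, f"{chain_id}:HEM", params, radii_table, equilibration_cutoff
    )


def mean_sasa(trace: SASATrace, t_start: float = 1.0, t_end: float = 133.0) -> float:
    """Time-averaged SASA (nm^2) over the averaging window (default 1-133 ns)."""
    return window_mean(trace.times, trace.values, t_start, t_end)
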