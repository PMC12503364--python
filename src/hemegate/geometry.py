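"""Core geometric computations on trajectories.

Distance traces, iron out-of-plane displacement relative to the pyrrole-N
plane, Kabsch least-squares superposition RMSD, and aromatic-stacking
descriptors (centroid distance, interplanar angle, lateral offset).

Units: all coordinates and distances are nm; stacking descriptors are
reported in Angstrom, the unit the structural literature uses for ring
geometry (1 nm = 10 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_io import Trajectory

__all__ = [
    "DistanceTrace",
    "DisplacementTrace",
    "StackingGeometry",
    "StackingCutoffs",
    "distance_trace",
    "mean_distance",
    "window_mean",
    "iron_plane_displacement",
    "kabsch_rotation",
    "kabsch_rmsd",
    "rmsd_trace",
    "stacking_geometry",
]

DEFAULT_EQUILIBRATION_NS = 1.0


@dataclass
class DistanceTrace:
    """Inter-atom distance time series (nm) with an equilibration cutoff.

    The *analyzed* view excludes frames before ``equilibration_cutoff`` ns;
    every downstream statistic (event detection, means, maxima) operates on
    the analyzed view only.
    """

    label: str
    times: np.ndarray  # ns
    values: np.ndarray  # nm, non-negative
    equilibration_cutoff: float = DEFAULT_EQUILIBRATION_NS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def analyzed(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) restricted to t >= equilibration_cutoff."""
        mask = self.times >= self.equilibration_cutoff
        return self.times[mask], self.values[mask]

    @property
    def total_time(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0


@dataclass
class DisplacementTrace:
    """Signed Fe out-of-plane displacement (nm).

    Positive values put the iron on the proximal-histidine side of the
    pyrrole-N plane (toward HisF8), the direction of T-state heme doming.
    ``magnitudes`` is the point-to-point |Fe - centroid| distance;
    ``perpendicular`` the projection onto the least-squares plane normal.
    The signed default value is sign x |Fe - centroid|.
    """

    times: np.ndarray
    values: np.ndarray  # signed, nm
    perpendicular: np.ndarray = field(default=None)  # type: ignore[assignment]
    equilibration_cutoff: float = DEFAULT_EQUILIBRATION_NS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.perpendicular is None:
            self.perpendicular = np.abs(self.values)
        self.perpendicular = np.asarray(self.perpendicular, dtype=float)

    def analyzed(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.times >= self.equilibration_cutoff
        return self.times[mask], self.values[mask]


@dataclass(frozen=True)
class StackingCutoffs:
    """Classification cutoffs for ring-ring geometry (Angstrom / degrees)."""

    parallel_max_angle: float = 30.0
    parallel_max_distance: float = 5.5
    t_shaped_min_angle: float = 60.0
    t_shaped_max_distance: float = 6.0


@dataclass(frozen=True)
class StackingGeometry:
    """Ring-pair descriptors: centroid distance, interplanar angle, offset (A)."""

    centroid_distance: float  # Angstrom
    interplanar_angle: float  # degrees, folded to [0, 90]
    offset: float  # Angstrom, lateral centroid displacement in ring-a plane
    stacking_class: str  # "parallel-displaced" | "T-shaped" | "none"


def distance_trace(
    traj: Trajectory,
    atom_a: int,
    atom_b: int,
    *,
    label: str = "",
    equilibration_cutoff: float = DEFAULT_EQUILIBRATION_NS,
    box_lengths: Sequence[float] | None = None,
) -> DistanceTrace:
    """Per-frame Euclidean distance between two atoms.

    No periodic-image correction is applied by default: intra-protein atom
    pairs in a ~10 nm box never span an image.  Passing ``box_lengths``
    (nm, orthorhombic) enables minimum-image distances for the rare case
    where it matters.
    """
    n = traj.n_atoms
    for idx in (atom_a, atom_b):
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} outside topology (n_atoms={n})")
    delta = traj.coordinates[:, atom_a, :] - traj.coordinates[:, atom_b, :]
    if box_lengths is not None:
        box = np.asarray(box_lengths, dtype=float)
        delta = delta - box * np.round(delta / box)
    values = np.linalg.norm(delta, axis=1)
    return DistanceTrace(
        label=label or f"atom{atom_a}-atom{atom_b}",
        times=traj.times.copy(),
        values=values,
        equilibration_cutoff=equilibration_cutoff,
    )


def window_mean(times: np.ndarray, values: np.ndarray, t_start: float, t_end: float) -> float:
    """Arithmetic mean of ``values`` over frames with t_start <= t <= t_end."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    mask = (times >= t_start) & (times <= t_end)
    if not np.any(mask):
        raise ValueError(f"no frames in window [{t_start}, {t_end}] ns")
    return float(values[mask].mean())


def mean_distance(trace: DistanceTrace, t_start: float = 1.0, t_end: float = 133.0) -> float:
    """Mean distance (nm) over the averaging window (default 1-133 ns)."""
    return window_mean(trace.times, trace.values, t_start, t_end)


def _plane_fit(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Least-squares plane -> (centroid, unit normal, RMS residual, singular values).

    The singular values of the centered point cloud diagnose degeneracy: a
    collinear set has s[1] ~ 0, in which case the plane normal is arbitrary.
    """
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return centroid, normal, rms, s


def iron_plane_displacement(
    traj: Trajectory,
    fe_index: int,
    pyrrole_indices: Sequence[int],
    proximal_ref_index: int,
    *,
    equilibration_cutoff: float = DEFAULT_EQUILIBRATION_NS,
) -> DisplacementTrace:
    """Signed displacement of the heme Fe from the pyrrole-N plane.

    Per frame: the centroid C of the four pyrrole nitrogens (unweighted --
    all four atoms are nitrogen, so mass weighting is a no-op), the
    least-squares plane normal n oriented toward the proximal-His reference
    atom, and the signed value sign((Fe - C) . n) x |Fe - C|.  The
    perpendicular projection |(Fe - C) . n| is carried alongside.
    """
    pyrrole = tuple(pyrrole_indices)
    if len(pyrrole) != 4:
        raise ValueError(f"need exactly 4 pyrrole nitrogens, got {len(pyrrole)}")
    signed = np.empty(traj.n_frames)
    perp = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        frame = traj.coordinates[k]
        n_pos = frame[list(pyrrole)]
        centroid, normal, _, s = _plane_fit(n_pos)
        if s[0] == 0.0 or s[1] < 1e-6 * s[0]:
            raise ValueError(f"degenerate pyrrole geometry at frame {k} (collinear nitrogens)")
        if np.dot(frame[proximal_ref_index] - centroid, normal) < 0:
            normal = -normal
        d = frame[fe_index] - centroid
        along = float(np.dot(d, normal))
        signed[k] = np.sign(along) * np.linalg.norm(d) if along != 0 else 0.0
        perp[k] = abs(along)
    return DisplacementTrace(
        times=traj.times.copy(),
        values=signed,
        perpendicular=perp,
        equilibration_cutoff=equilibration_cutoff,
    )


def kabsch_rotation(reference: np.ndarray, mobile: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (3x3) aligning centered ``mobile`` onto centered ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def kabsch_rmsd(
    reference: np.ndarray,
    frame: np.ndarray,
    selection: Sequence[int] | None = None,
) -> float:
    """RMSD (nm) after optimal least-squares superposition (rotation + translation).

    The superposition is computed on the same selection the RMSD is evaluated
    over; reflections are excluded (proper rotations only).
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(frame, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        ref = ref[sel]
        mob = mob[sel]
    if ref.shape != mob.shape:
        raise ValueError("reference and frame selections differ in shape")
    if len(ref) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    rot = kabsch_rotation(ref_c, mob_c)
    diff = mob_c @ rot.T - ref_c
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def rmsd_trace(
    traj: Trajectory,
    reference_frame: int,
    selection: Sequence[int],
    *,
    equilibration_cutoff: float = DEFAULT_EQUILIBRATION_NS,
) -> DistanceTrace:
    """Per-frame Kabsch RMSD (nm) against one reference frame, on a selection."""
    if not 0 <= reference_frame < traj.n_frames:
        raise IndexError(f"reference frame {reference_frame} outside trajectory")
    sel = np.asarray(selection, dtype=int)
    ref = traj.coordinates[reference_frame][sel]
    values = np.array([kabsch_rmsd(ref, traj.coordinates[k][sel]) for k in range(traj.n_frames)])
    return DistanceTrace(
        label=f"rmsd[{len(sel)} atoms vs frame {reference_frame}]",
        times=traj.times.copy(),
        values=values,
        equilibration_cutoff=equilibration_cutoff,
    )


def stacking_geometry(
    ring_a: np.ndarray,
    ring_b: np.ndarray,
    cutoffs: StackingCutoffs = StackingCutoffs(),
    *,
    max_planarity_rms: float = 0.03,  # nm (= 0.3 A)
) -> StackingGeometry:
    """Classify the geometry of two aromatic rings (coordinates in nm).

    Descriptors: centroid-centroid distance, angle between least-squares
    ring normals folded to [0, 90] deg, and the lateral offset of ring b's
    centroid in ring a's plane.  Classification (package defaults,
    configurable): parallel-displaced if angle < 30 deg and distance <
    5.5 A; T-shaped if angle > 60 deg and distance < 6.0 A; otherwise none.
    """
    ring_a = np.asarray(ring_a, dtype=float)
    ring_b = np.asarray(ring_b, dtype=float)
    for name, ring in (("a", ring_a), ("b", ring_b)):
        if len(ring) < 5:
            raise ValueError(f"ring {name} needs >= 5 atoms, got {len(ring)}")
        _, _, rms, _ = _plane_fit(ring)
        if rms > max_planarity_rms:
            raise ValueError(
                f"ring {name} is not planar (RMS out-of-plane {rms * 10:.2f} A > "
                f"{max_planarity_rms * 10:.1f} A)"
            )
    cen_a, n_a, _, _ = _plane_fit(ring_a)
    cen_b, n_b, _, _ = _plane_fit(ring_b)
    d_vec = cen_b - cen_a
    dist_a = float(np.linalg.norm(d_vec)) * 10.0  # nm -> Angstrom
    cosang = abs(float(np.dot(n_a, n_b)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    lateral = d_vec - np.dot(d_vec, n_a) * n_a
    offset_a = float(np.linalg.norm(lateral)) * 10.0
    if angle < cutoffs.parallel_max_angle and dist_a < cutoffs.parallel_max_distance:
        cls = "parallel-displaced"
    elif angle > cutoffs.t_shaped_min_angle and dist_a < cutoffs.t_shaped_max_distance:
        cls = "T-shaped"
    else:
        cls = "none"
    return StackingGeometry(
        centroid_distance=dist_a,
        interplanar_angle=angle,
        offset=offset_a,
        stacking_class=cls,
    )
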