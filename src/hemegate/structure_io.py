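"""Structure / trajectory input and site resolution.

Reads a PDB topology into a light :class:`StructureModel`, auto-detects heme
groups (Fe + four pyrrole nitrogens), resolves Perutz helical-notation sites
(E7, F8, E11, ...) to concrete atoms through a per-species :class:`SiteMap`,
and loads coordinate trajectories (XTC/TRR/DCD/multi-model PDB) via
MDAnalysis.  All coordinates are stored in nm (GROMACS convention); file
formats that use Angstrom are converted on read and write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "StructureError",
    "SiteResolutionError",
    "TrajectoryError",
    "HemeGroup",
    "StructureModel",
    "SiteEntry",
    "SiteMap",
    "Trajectory",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "resolve_site",
    "resolve_site_all",
    "write_table",
]

ANGSTROM_PER_NM = 10.0

#: residue names treated as solvent / ions and excluded from analysis contexts
SOLVENT_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP3", "SOL", "NA", "CL", "K", "MG", "CA2", "SOD", "CLA", "POT", "PO4"}
)

DEFAULT_HEME_RESNAMES = ("HEM", "HEME")
DEFAULT_FE_NAMES = ("FE",)
DEFAULT_PYRROLE_NAMES = ("NA", "NB", "NC", "ND")

SUBUNIT_CLASSES = ("alpha", "beta")

HELICAL_SITES = (
    "E7", "F8", "E11", "E10", "E3", "F4",
    "CE1", "CE3", "CE4", "C6", "C7", "FG4", "G1", "G4",
)


class StructureError(ValueError):
    """Raised for malformed or inconsistent structures (e.g. broken hemes)."""


class SiteResolutionError(KeyError):
    """Raised when a helical site cannot be resolved to a unique atom."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class TrajectoryError(ValueError):
    """Raised for unreadable trajectories or topology/trajectory mismatches."""


@dataclass(frozen=True)
class HemeGroup:
    """One heme: its chain, Fe atom index and the 4 pyrrole-N atom indices."""

    chain_id: str
    residue_index: int
    fe_index: int
    pyrrole_indices: tuple[int, int, int, int]


@dataclass
class StructureModel:
    """Atoms of one structure with heme-group bookkeeping.

    Atom identity is keyed on ``(chain_id, residue_index, atom_name)``;
    positions are in nm.  ``chain_classes`` maps chain id to subunit class
    ("alpha"/"beta") and normally comes from the :class:`SiteMap`.
    """

    chain_ids: np.ndarray
    residue_indices: np.ndarray
    residue_names: np.ndarray
    atom_names: np.ndarray
    positions: np.ndarray  # (n_atoms, 3), nm
    hemes: list[HemeGroup] = field(default_factory=list)
    chain_classes: dict[str, str] | None = None
    source_path: Path | None = None

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        if not (len(self.chain_ids) == len(self.residue_indices)
                == len(self.residue_names) == n == len(self.positions)):
            raise StructureError("inconsistent atom-array lengths")
        seen: dict[tuple[str, int, str], int] = {}
        for i in range(n):
            key = (str(self.chain_ids[i]), int(self.residue_indices[i]), str(self.atom_names[i]))
            if key in seen:
                raise StructureError(f"duplicate atom {key}")
            seen[key] = i
        self._index = seen
        for heme in self.hemes:
            if len(heme.pyrrole_indices) != 4:
                raise StructureError(
                    f"heme in chain {heme.chain_id} has "
                    f"{len(heme.pyrrole_indices)} pyrrole nitrogens, expected 4"
                )
            for idx in (heme.fe_index, *heme.pyrrole_indices):
                if not 0 <= idx < n:
                    raise StructureError(f"heme in chain {heme.chain_id} references missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for c in self.chain_ids:
            if c not in out:
                out.append(str(c))
        return out

    def atom_index(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        key = (chain_id, int(residue_index), atom_name)
        try:
            return self._index[key]
        except KeyError:
            raise SiteResolutionError(
                f"atom {atom_name} of residue {residue_index} in chain {chain_id} not found"
            ) from None

    def residue_atom_indices(self, chain_id: str, residue_index: int) -> np.ndarray:
        mask = (self.chain_ids == chain_id) & (self.residue_indices == residue_index)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SiteResolutionError(f"residue {residue_index} in chain {chain_id} not found")
        return idx

    def residue_name(self, chain_id: str, residue_index: int) -> str:
        return str(self.residue_names[self.residue_atom_indices(chain_id, residue_index)[0]])

    def heme_for_chain(self, chain_id: str) -> HemeGroup:
        for heme in self.hemes:
            if heme.chain_id == chain_id:
                return heme
        raise StructureError(f"no heme group in chain {chain_id}")

    def analysis_context_indices(self, exclude_resnames: Iterable[str] = SOLVENT_RESNAMES) -> np.ndarray:
        """Protein + heme atom indices (solvent and ions excluded)."""
        excluded = set(exclude_resnames)
        mask = np.array([rn not in excluded for rn in self.residue_names], dtype=bool)
        return np.flatnonzero(mask)


@dataclass(frozen=True)
class SiteEntry:
    residue_index: int
    expected_residue_name: str | None = None


@dataclass
class SiteMap:
    """Per-species mapping of helical sites to residues, plus chain classes."""

    species: str
    chain_classes: dict[str, str]
    entries: dict[tuple[str, str], SiteEntry]

    def __post_init__(self) -> None:
        for chain, cls in self.chain_classes.items():
            if cls not in SUBUNIT_CLASSES:
                raise StructureError(f"chain {chain}: unknown subunit class {cls!r}")
        for (cls, site) in self.entries:
            if cls not in SUBUNIT_CLASSES:
                raise StructureError(f"site map entry has unknown subunit class {cls!r}")

    def chains_of(self, subunit_class: str) -> list[str]:
        return [c for c, cls in self.chain_classes.items() if cls == subunit_class]

    def entry(self, subunit_class: str, site: str) -> SiteEntry:
        try:
            return self.entries[(subunit_class, site)]
        except KeyError:
            raise SiteResolutionError(
                f"site {site} is not mapped for subunit class {subunit_class} "
                f"(species {self.species})"
            ) from None

    def has_site(self, subunit_class: str, site: str) -> bool:
        return (subunit_class, site) in self.entries

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SiteMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        entries: dict[tuple[str, str], SiteEntry] = {}
        for subunit, sites in raw.get("sites", {}).items():
            for site, spec in sites.items():
                entries[(subunit, str(site))] = SiteEntry(
                    residue_index=int(spec["resid"]),
                    expected_residue_name=spec.get("resname"),
                )
        return cls(
            species=str(raw["species"]),
            chain_classes={str(k): str(v) for k, v in raw["chains"].items()},
            entries=entries,
        )

    def to_yaml(self, path: str | Path) -> None:
        sites: dict[str, dict[str, dict]] = {}
        for (subunit, site), entry in self.entries.items():
            block = sites.setdefault(subunit, {})
            block[site] = {"resid": entry.residue_index}
            if entry.expected_residue_name:
                block[site]["resname"] = entry.expected_residue_name
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"species": self.species, "chains": self.chain_classes, "sites": sites},
                fh, sort_keys=False,
            )


@dataclass
class Trajectory:
    """In-memory trajectory: frames x atoms x 3 in nm, times in ns."""

    times: np.ndarray  # (n_frames,), ns, strictly increasing
    coordinates: np.ndarray  # (n_frames, n_atoms, 3), nm
    frame_spacing: float = 0.2  # ns

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError("coordinates must have shape (frames, atoms, 3)")
        if len(self.times) != len(self.coordinates):
            raise TrajectoryError("times and coordinate frames differ in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def total_time(self) -> float:
        return float(self.times[-1]) if self.n_frames else 0.0


def _mda_universe(*paths: str):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*paths)


def read_structure(
    path: str | Path,
    *,
    heme_resnames: Sequence[str] = DEFAULT_HEME_RESNAMES,
    fe_names: Sequence[str] = DEFAULT_FE_NAMES,
    pyrrole_names: Sequence[str] = DEFAULT_PYRROLE_NAMES,
    chain_classes: Mapping[str, str] | None = None,
) -> StructureModel:
    """Read a PDB topology and auto-detect heme groups.

    Heme detection is name-based (configurable residue and atom name sets,
    default ``HEM``/``HEME`` with Fe atom ``FE`` and pyrrole nitrogens
    ``NA NB NC ND``).  A heme missing its Fe or without exactly four pyrrole
    nitrogens raises :class:`StructureError` naming the offending chain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    u = _mda_universe(str(path))
    atoms = u.atoms
    if hasattr(atoms, "chainIDs") and any(str(c).strip() for c in atoms.chainIDs):
        chain_ids = np.array([str(c).strip() or str(s) for c, s in zip(atoms.chainIDs, atoms.segids)])
    else:
        chain_ids = np.array([str(s).strip() for s in atoms.segids])
    model = StructureModel(
        chain_ids=chain_ids,
        residue_indices=np.asarray(atoms.resids, dtype=int),
        residue_names=np.array([str(r).strip() for r in atoms.resnames]),
        atom_names=np.array([str(n).strip() for n in atoms.names]),
        positions=atoms.positions.astype(float) / ANGSTROM_PER_NM,
        chain_classes=dict(chain_classes) if chain_classes else None,
        source_path=path,
    )
    model.hemes = _detect_hemes(model, heme_resnames, fe_names, pyrrole_names)
    return model


def _detect_hemes(
    model: StructureModel,
    heme_resnames: Sequence[str],
    fe_names: Sequence[str],
    pyrrole_names: Sequence[str],
) -> list[HemeGroup]:
    hemes: list[HemeGroup] = []
    heme_set = set(heme_resnames)
    seen: set[tuple[str, int]] = set()
    for i in range(model.n_atoms):
        if model.residue_names[i] not in heme_set:
            continue
        key = (str(model.chain_ids[i]), int(model.residue_indices[i]))
        if key in seen:
            continue
        seen.add(key)
        chain, resid = key
        idx = model.residue_atom_indices(chain, resid)
        names = model.atom_names[idx]
        fe = idx[np.isin(names, fe_names)]
        pyrrole = idx[np.isin(names, pyrrole_names)]
        if fe.size != 1:
            raise StructureError(
                f"heme in chain {chain} (residue {resid}): expected 1 Fe atom "
                f"({'/'.join(fe_names)}), found {fe.size}"
            )
        if pyrrole.size != 4:
            raise StructureError(
                f"heme in chain {chain} (residue {resid}): expected 4 pyrrole "
                f"nitrogens ({'/'.join(pyrrole_names)}), found {pyrrole.size}"
            )
        hemes.append(HemeGroup(chain, resid, int(fe[0]), tuple(int(j) for j in pyrrole)))
    return hemes


def resolve_site(
    model: StructureModel,
    site_map: SiteMap,
    subunit_class: str,
    site: str,
    atom_name: str,
    chain_id: str | None = None,
) -> int:
    """Resolve (subunit class, helical site, atom name) to one atom index.

    Validation is strict: an unmapped site, a residue whose name contradicts
    the map's ``expected_residue_name`` (e.g. the map expects Trp at CE4 but
    the structure holds Phe), or a missing atom all raise
    :class:`SiteResolutionError`.  ``chain_id`` selects among the several
    chains of one subunit class and is required when the class is ambiguous.
    """
    entry = site_map.entry(subunit_class, site)
    chains = site_map.chains_of(subunit_class)
    if chain_id is None:
        if len(chains) != 1:
            raise SiteResolutionError(
                f"subunit class {subunit_class} has chains {chains}; pass chain_id"
            )
        chain_id = chains[0]
    elif chain_id not in chains:
        raise SiteResolutionError(
            f"chain {chain_id} is not a {subunit_class} chain in map for {site_map.species}"
        )
    actual = model.residue_name(chain_id, entry.residue_index)
    if entry.expected_residue_name and actual != entry.expected_residue_name:
        raise SiteResolutionError(
            f"site {site} ({subunit_class}, chain {chain_id}): map expects residue "
            f"{entry.expected_residue_name} at {entry.residue_index} but structure has {actual}"
        )
    return model.atom_index(chain_id, entry.residue_index, atom_name)


def resolve_site_all(
    model: StructureModel,
    site_map: SiteMap,
    subunit_class: str,
    site: str,
    atom_name: str,
) -> dict[str, int]:
    """Resolve a site on every chain of a subunit class -> {chain_id: atom index}."""
    return {
        chain: resolve_site(model, site_map, subunit_class, site, atom_name, chain_id=chain)
        for chain in site_map.chains_of(subunit_class)
    }


def read_trajectory(
    topology: StructureModel,
    path: str | Path,
    *,
    frame_spacing: float = 0.2,
) -> Trajectory:
    """Load a trajectory (XTC/TRR/DCD/multi-model PDB) against a topology.

    Coordinates come back in nm whatever the source format's native unit.
    Times are taken from the file only for formats that store a genuine
    per-frame time axis (XTC/TRR) and where that axis is strictly
    increasing; for everything else (PDB, DCD, ...) readers fabricate
    times from a default dt, so times are synthesized as
    ``frame_index * frame_spacing`` ns instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if topology.source_path is None:
        raise TrajectoryError("topology has no source file to key trajectory loading on")
    try:
        u = _mda_universe(str(topology.source_path), str(path))
    except Exception as exc:  # MDAnalysis raises assorted types on mismatch
        raise TrajectoryError(f"cannot load trajectory {path}: {exc}") from exc
    if u.atoms.n_atoms != topology.n_atoms:
        raise TrajectoryError(
            f"trajectory atom count {u.atoms.n_atoms} != topology atom count {topology.n_atoms}"
        )
    frames = []
    times_ps = []
    for ts in u.trajectory:
        frames.append(ts.positions.astype(float) / ANGSTROM_PER_NM)
        times_ps.append(float(ts.time))
    coords = np.array(frames)
    times = np.asarray(times_ps) / 1000.0  # ps -> ns
    has_real_times = path.suffix.lower() in {".xtc", ".trr"}
    if not has_real_times or (len(times) > 1 and np.any(np.diff(times) <= 0)):
        times = np.arange(len(frames)) * frame_spacing
    return Trajectory(times=times, coordinates=coords, frame_spacing=frame_spacing)


def write_trajectory(
    topology: StructureModel,
    coordinates_nm: np.ndarray,
    path: str | Path,
    *,
    frame_spacing: float = 0.2,
) -> Path:
    """Write frames (nm) to any MDAnalysis-writable trajectory format (by suffix)."""
    import MDAnalysis as mda

    coords = np.asarray(coordinates_nm, dtype=float)
    if coords.ndim != 3 or coords.shape[1] != topology.n_atoms:
        raise TrajectoryError("coordinate array does not match topology atom count")
    path = Path(path)
    writer_kwargs: dict = {}
    if path.suffix.lower() == ".xtc":
        # 4 decimals in nm (1e-4 nm quantization) so planted distances
        # survive the round trip well inside the 1e-3 nm tolerance
        writer_kwargs["precision"] = 4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(topology.n_atoms, trajectory=True)
        u.add_TopologyAttr("names", list(topology.atom_names))
        with mda.Writer(str(path), n_atoms=topology.n_atoms, **writer_kwargs) as w:
            for k, frame in enumerate(coords):
                u.atoms.positions = frame * ANGSTROM_PER_NM
                u.trajectory.ts.frame = k
                u.trajectory.ts.dt = frame_spacing * 1000.0
                u.trajectory.ts.time = k * frame_spacing * 1000.0
                w.write(u.atoms)
    return path


def write_table(path: str | Path, table, params: Mapping[str, object] | None = None) -> Path:
    """Write a pandas DataFrame as TSV with a ``#``-comment parameter header."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (params or {}).items():
            fh.write(f"# {key} = {value}\n")
        table.to_csv(fh, sep="\t", index=False)
    return path
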