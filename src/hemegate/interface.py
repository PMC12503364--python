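"""alpha1-beta2 interfacial contact analysis.

Four canonical atom-pair contact sites define the interface (letters A-D
internally; reports also carry the 1/2/3 numbering used for the three
sites shared by both species, with the bovine-only Thr/Arg hydrogen bond
reported alongside site 2):

    A / site 1  Asp(a1 G1)  CG  -> Asn(b2 G4)  ND2   hydrogen bond
    B / site 2  Tyr(a1 C7)  CZ  -> Arg(b2 C6)  CZ    stacking
    C / site 3  Arg(a1 FG4) CD  -> Arg(b2 C6)  CB    stacking
    D / site 2' Thr(a1 C6)  OG  -> Arg(b2 C6)  CZ    hydrogen bond, bovine-like only

A trout-like species substitutes Ala for Thr at a1 C6 and so lacks site D:
requesting it against such a site map is an applicability error, giving
3 sites instead of 4.  Loosening of these contacts — especially large
excursions of the Arg b2 C6 guanidinium at site 2 — precedes tetramer
disassembly, which is why per-replicate maxima and the local backbone-RMSD
drift (OLS slope over the analysis window) are the reported statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DistanceTrace, distance_trace, rmsd_trace
from .structure_io import (
    SiteMap,
    SiteResolutionError,
    StructureModel,
    Trajectory,
    resolve_site,
)

__all__ = [
    "InterfaceSite",
    "CANONICAL_SITES",
    "InterfaceSelection",
    "SiteApplicabilityError",
    "site_distance_trace",
    "max_site_distance",
    "interface_selection",
    "interface_rmsd_slope",
]

INTERFACE_BACKBONE_ATOMS = ("N", "CA", "O")
INTERFACE_RESIDUE_SITES = (
    ("alpha", "C6"), ("alpha", "C7"), ("alpha", "FG4"),
    ("alpha", "G1"), ("beta", "C6"), ("beta", "G4"),
)
#: documented size of the full bovine-style backbone index group
FULL_SELECTION_N_ATOMS = 48


class SiteApplicabilityError(ValueError):
    """Raised when a contact site does not exist for the given species map."""


@dataclass(frozen=True)
class InterfaceSite:
    site_id: str  # A-D
    report_label: str  # site 1 / site 2 / site 3 / site 2'
    side_a: tuple[str, str, str]  # (subunit class, helical site, atom name) on alpha1
    side_b: tuple[str, str, str]  # on beta2
    interaction_class: str  # hydrogen-bond | stacking
    requires_sites: tuple[tuple[str, str, str], ...] = ()  # (class, site, resname) prerequisites


CANONICAL_SITES: dict[str, InterfaceSite] = {
    "A": InterfaceSite("A", "site 1", ("alpha", "G1", "CG"), ("beta", "G4", "ND2"), "hydrogen-bond"),
    "B": InterfaceSite("B", "site 2", ("alpha", "C7", "CZ"), ("beta", "C6", "CZ"), "stacking"),
    "C": InterfaceSite("C", "site 3", ("alpha", "FG4", "CD"), ("beta", "C6", "CB"), "stacking"),
    "D": InterfaceSite(
        "D", "site 2'", ("alpha", "C6", "OG"), ("beta", "C6", "CZ"), "hydrogen-bond",
        requires_sites=(("alpha", "C6", "THR"),),
    ),
}


def _check_applicability(model: StructureModel, site_map: SiteMap, site: InterfaceSite) -> None:
    for subunit, helical, resname in site.requires_sites:
        if not site_map.has_site(subunit, helical):
            raise SiteApplicabilityError(
                f"interface site {site.site_id} needs {subunit} {helical} mapped "
                f"(species {site_map.species})"
            )
        entry = site_map.entry(subunit, helical)
        for chain in site_map.chains_of(subunit):
            actual = model.residue_name(chain, entry.residue_index)
            if actual != resname:
                raise SiteApplicabilityError(
                    f"interface site {site.site_id} requires {resname} at {subunit} {helical}; "
                    f"species {site_map.species} has {actual} (no such contact)"
                )


def site_distance_trace(
    traj: Trajectory,
    model: StructureModel,
    site_map: SiteMap,
    site: InterfaceSite,
    alpha1_chain: str,
    beta2_chain: str,
    *,
    equilibration_cutoff: float = 1.0,
) -> DistanceTrace:
    """Per-frame distance (nm) between the two named atoms of one contact site."""
    _check_applicability(model, site_map, site)
    sub_a, hel_a, atom_a = site.side_a
    sub_b, hel_b, atom_b = site.side_b
    try:
        ia = resolve_site(model, site_map, sub_a, hel_a, atom_a, chain_id=alpha1_chain)
        ib = resolve_site(model, site_map, sub_b, hel_b, atom_b, chain_id=beta2_chain)
    except SiteResolutionError as exc:
        raise SiteApplicabilityError(
            f"interface site {site.site_id} not resolvable for {site_map.species}: {exc}"
        ) from exc
    label = (
        f"{site.site_id} {alpha1_chain}:{hel_a}:{atom_a} - {beta2_chain}:{hel_b}:{atom_b}"
    )
    return distance_trace(
        traj, ia, ib, label=label, equilibration_cutoff=equilibration_cutoff
    )


def max_site_distance(trace: DistanceTrace) -> float:
    """Maximum distance (nm) over the analyzed frames (t >= cutoff)."""
    _, values = trace.analyzed()
    if len(values) == 0:
        raise ValueError("trace has no frames past the equilibration cutoff")
    return float(values.max())


@dataclass(frozen=True)
class InterfaceSelection:
    """Backbone (N, CA, O) atom indices of the six interfacial residues."""

    atom_indices: tuple[int, ...]
    residues: tuple[tuple[str, int], ...]  # (chain, resid)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


def interface_selection(
    model: StructureModel,
    site_map: SiteMap,
    alpha1_chain: str,
    beta2_chain: str,
    *,
    expected_n_atoms: int | None = None,
) -> InterfaceSelection:
    """Backbone selection over a1 C6/C7/FG4/G1 and b2 C6/G4.

    ``expected_n_atoms`` (e.g. the documented 48 for the full bovine-style
    index group) enables a hard count check when the residue content is
    known a priori.
    """
    indices: list[int] = []
    residues: list[tuple[str, int]] = []
    for subunit, helical in INTERFACE_RESIDUE_SITES:
        if not site_map.has_site(subunit, helical):
            continue  # trout-like maps may omit nothing here, but stay tolerant
        chain = alpha1_chain if subunit == "alpha" else beta2_chain
        entry = site_map.entry(subunit, helical)
        residues.append((chain, entry.residue_index))
        for atom in INTERFACE_BACKBONE_ATOMS:
            indices.append(model.atom_index(chain, entry.residue_index, atom))
    if expected_n_atoms is not None and len(indices) != expected_n_atoms:
        raise ValueError(
            f"interface selection has {len(indices)} atoms, expected {expected_n_atoms}"
        )
    return InterfaceSelection(atom_indices=tuple(indices), residues=tuple(residues))


def interface_rmsd_slope(
    traj: Trajectory,
    selection: InterfaceSelection,
    reference_frame: int = 0,
    *,
    t_start: float = 1.0,
    t_end: float = 133.0,
) -> tuple[float, float, DistanceTrace]:
    """OLS drift of the local interface backbone RMSD over the window.

    Returns (slope nm/ns, intercept nm, the underlying RMSD trace).  The
    superposition uses the interface selection itself, so the fit measures
    internal loosening of the contact region, not global tumbling.
    """
    from .stats import simple_linear_regression

    trace = rmsd_trace(traj, reference_frame, selection.atom_indices)
    mask = (trace.times >= t_start) & (trace.times <= t_end)
    if np.count_nonzero(mask) < 3:
        raise ValueError(f"fewer than 3 frames in window [{t_start}, {t_end}] ns")
    fit = simple_linear_regression(trace.times[mask], trace.values[mask])
    return fit.slope, fit.intercept, trace
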