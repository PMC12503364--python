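"""Config-driven end-to-end analysis of a topology + replicate trajectories.

One :func:`run_analysis` call reproduces, per treatment (species x
protonation state), the full post-processing battery: per-chain swing-out
records and treatment event counts / normalized swing times, pooled
Fe-L1 (HisF8 Ne - Fe) window means per chain class, iron out-of-plane
displacement averages, interface per-site per-replicate maxima, local
interface backbone RMSD with its OLS drift, and SASA window averages for
E11 and the heme in the alpha chains.  Outputs are TSV tables plus a JSON
run manifest recording every parameter and input checksum, so reruns are
checkable byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import geometry as geo
from . import interface as ifc
from . import sasa as sa
from .structure_io import (
    SiteMap,
    StructureModel,
    read_structure,
    read_trajectory,
    resolve_site,
    write_table,
)

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "run_analysis",
    "compare_treatments",
    "compare_crystal_structures",
]

log = logging.getLogger("hemegate.pipeline")


@dataclass
class AnalysisConfig:
    """Everything one treatment's analysis needs; loadable from YAML."""

    species: str
    treatment: str
    site_map: Path
    topology: Path
    trajectories: list[Path]
    output_dir: Path
    swing_threshold_nm: float = 0.7
    equilibration_ns: float = 1.0
    window_ns: tuple[float, float] = (1.0, 133.0)
    frame_spacing_ns: float = 0.2
    return_dwell_ns: float = 5.0
    reference_total_time_ns: float | None = None  # default: this treatment's own total
    sasa_probe_nm: float = 0.14
    sasa_points: int = 960
    sasa_radii: str = "bondi"
    alpha1_chain: str | None = None  # default: first alpha chain
    beta2_chain: str | None = None  # default: last beta chain
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def _p(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        return cls(
            species=raw["species"],
            treatment=raw["treatment"],
            site_map=_p(raw["site_map"]),
            topology=_p(raw["topology"]),
            trajectories=[_p(p) for p in raw["trajectories"]],
            output_dir=_p(raw.get("output_dir", "analysis_out")),
            swing_threshold_nm=float(raw.get("swing_threshold_nm", 0.7)),
            equilibration_ns=float(raw.get("equilibration_ns", 1.0)),
            window_ns=tuple(raw.get("window_ns", (1.0, 133.0))),
            frame_spacing_ns=float(raw.get("frame_spacing_ns", 0.2)),
            return_dwell_ns=float(raw.get("return_dwell_ns", 5.0)),
            reference_total_time_ns=raw.get("reference_total_time_ns"),
            sasa_probe_nm=float(raw.get("sasa_probe_nm", 0.14)),
            sasa_points=int(raw.get("sasa_points", 960)),
            sasa_radii=str(raw.get("sasa_radii", "bondi")),
            alpha1_chain=raw.get("alpha1_chain"),
            beta2_chain=raw.get("beta2_chain"),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class ReportBundle:
    """All tables of one treatment run (also written as TSV under output_dir)."""

    treatment: str
    swing_records: pd.DataFrame
    treatment_summary: ev.TreatmentSummary
    fe_l1_means: pd.DataFrame  # one row per chain-replicate trace
    iron_displacement: pd.DataFrame
    interface_maxima: pd.DataFrame
    interface_rmsd_fits: pd.DataFrame
    sasa_averages: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class PipelineError(RuntimeError):
    """A module error with the pipeline stage attached."""


def _stage(name):
    import contextlib

    @contextlib.contextmanager
    def cm():
        log.info("stage: %s", name)
        try:
            yield
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r}: {exc}") from exc

    return cm()


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full post-processing battery for one treatment."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0, t1 = config.window_ns

    with _stage("load topology and site map"):
        site_map = SiteMap.from_yaml(config.site_map)
        model = read_structure(config.topology, chain_classes=site_map.chain_classes)
        alpha_chains = site_map.chains_of("alpha")
        beta_chains = site_map.chains_of("beta")
        a1 = config.alpha1_chain or alpha_chains[0]
        b2 = config.beta2_chain or beta_chains[-1]

    with _stage("load trajectories"):
        trajectories = []
        for path in config.trajectories:
            if not Path(path).exists():
                raise FileNotFoundError(f"trajectory not found: {path}")
            traj = read_trajectory(model, path, frame_spacing=config.frame_spacing_ns)
            if traj.total_time < t1:
                log.warning("trajectory %s ends at %.1f ns, window truncated", path, traj.total_time)
            trajectories.append(traj)

    sasa_params = sa.SASAParams(
        probe_radius=config.sasa_probe_nm, n_sphere_points=config.sasa_points,
        radii_set=config.sasa_radii,
    )

    with _stage("swing-out events"):
        records: list[ev.SwingRecord] = []
        for r, traj in enumerate(trajectories):
            rep = f"rep{r + 1}"
            for chain in alpha_chains:
                i_ne = resolve_site(model, site_map, "alpha", "E7", "NE2", chain_id=chain)
                i_fe = model.heme_for_chain(chain).fe_index
                trace = geo.distance_trace(
                    traj, i_ne, i_fe,
                    label=f"{rep}:{chain} E7:NE2-FE",
                    equilibration_cutoff=config.equilibration_ns,
                )
                records.append(ev.detect_swing(
                    trace, threshold=config.swing_threshold_nm,
                    down_threshold=config.swing_threshold_nm,
                    dwell_min=config.return_dwell_ns,
                    replicate_id=rep, chain_id=chain,
                ))
        per_rep_times = {r.replicate_id: r.replicate_total_time for r in records}
        treatment_total = sum(per_rep_times.values())
        reference_total = config.reference_total_time_ns or treatment_total
        summary = ev.count_events(records, reference_total, treatment=config.treatment)
        summary.normalized_swing_times = ev.normalized_swing_times(
            records, max(per_rep_times.values()), reference_total, treatment_total,
        )
        swing_df = pd.DataFrame([{
            "replicate": r.replicate_id, "chain": r.chain_id,
            "swung_out": r.swung_out,
            "first_exceed_ns": r.first_exceed_time,
            "n_excursions": len(r.excursions),
            "returned_down": r.returned_down,
            "replicate_total_ns": r.replicate_total_time,
        } for r in records])

    with _stage("Fe-L1 distances"):
        fe_l1_rows = []
        for r, traj in enumerate(trajectories):
            rep = f"rep{r + 1}"
            for cls, chains in (("alpha", alpha_chains), ("beta", beta_chains)):
                for chain in chains:
                    i_ne = resolve_site(model, site_map, cls, "F8", "NE2", chain_id=chain)
                    i_fe = model.heme_for_chain(chain).fe_index
                    trace = geo.distance_trace(traj, i_ne, i_fe,
                                               equilibration_cutoff=config.equilibration_ns)
                    fe_l1_rows.append({
                        "replicate": rep, "chain": chain, "chain_class": cls,
                        "mean_nm": geo.mean_distance(trace, t0, min(t1, traj.total_time)),
                    })
        fe_l1_df = pd.DataFrame(fe_l1_rows)

    with _stage("iron displacement"):
        disp_rows = []
        for r, traj in enumerate(trajectories):
            rep = f"rep{r + 1}"
            for chain in alpha_chains:
                heme = model.heme_for_chain(chain)
                i_prox = resolve_site(model, site_map, "alpha", "F8", "NE2", chain_id=chain)
                disp = geo.iron_plane_displacement(
                    traj, heme.fe_index, heme.pyrrole_indices, i_prox,
                    equilibration_cutoff=config.equilibration_ns,
                )
                disp_rows.append({
                    "replicate": rep, "chain": chain,
                    "mean_signed_nm": geo.window_mean(disp.times, disp.values, t0,
                                                      min(t1, traj.total_time)),
                    "mean_perpendicular_nm": geo.window_mean(disp.times, disp.perpendicular,
                                                             t0, min(t1, traj.total_time)),
                })
        disp_df = pd.DataFrame(disp_rows)

    with _stage("interface sites"):
        max_rows = []
        for r, traj in enumerate(trajectories):
            rep = f"rep{r + 1}"
            for site in ifc.CANONICAL_SITES.values():
                try:
                    trace = ifc.site_distance_trace(
                        traj, model, site_map, site, a1, b2,
                        equilibration_cutoff=config.equilibration_ns,
                    )
                except ifc.SiteApplicabilityError:
                    continue
                max_rows.append({
                    "replicate": rep, "site": site.site_id,
                    "report_label": site.report_label,
                    "interaction": site.interaction_class,
                    "max_nm": ifc.max_site_distance(trace),
                })
        maxima_df = pd.DataFrame(max_rows)

    with _stage("interface RMSD"):
        selection = ifc.interface_selection(model, site_map, a1, b2)
        fit_rows = []
        for r, traj in enumerate(trajectories):
            slope, intercept, _ = ifc.interface_rmsd_slope(
                traj, selection, 0, t_start=t0, t_end=min(t1, traj.total_time),
            )
            fit_rows.append({"replicate": f"rep{r + 1}", "slope_nm_per_ns": slope,
                             "intercept_nm": intercept, "n_atoms": selection.n_atoms})
        rmsd_df = pd.DataFrame(fit_rows)

    with _stage("SASA"):
        sasa_rows = []
        for r, traj in enumerate(trajectories):
            rep = f"rep{r + 1}"
            for chain in alpha_chains:
                e11 = sa.residue_sasa_trace(
                    traj, model, site_map, "alpha", chain, "E11", sasa_params,
                    equilibration_cutoff=config.equilibration_ns,
                )
                heme = sa.heme_sasa_trace(traj, model, chain, sasa_params,
                                          equilibration_cutoff=config.equilibration_ns)
                sasa_rows.append({
                    "replicate": rep, "chain": chain,
                    "e11_mean_nm2": sa.mean_sasa(e11, t0, min(t1, traj.total_time)),
                    "heme_mean_nm2": sa.mean_sasa(heme, t0, min(t1, traj.total_time)),
                })
        sasa_df = pd.DataFrame(sasa_rows)

    with _stage("write bundle"):
        params = {
            "species": config.species, "treatment": config.treatment,
            "swing_threshold_nm": config.swing_threshold_nm,
            "equilibration_ns": config.equilibration_ns,
            "window_ns": list(config.window_ns),
            "return_dwell_ns": config.return_dwell_ns,
            "reference_total_time_ns": reference_total,
            "treatment_total_time_ns": treatment_total,
            "longest_replicate_ns": max(per_rep_times.values()),
            "sasa_probe_nm": config.sasa_probe_nm,
            "sasa_points": config.sasa_points,
            "sasa_radii": config.sasa_radii,
            "alpha1_chain": a1, "beta2_chain": b2,
        }
        write_table(out / "swing_records.tsv", swing_df, params)
        write_table(out / "fe_l1_means.tsv", fe_l1_df, params)
        write_table(out / "iron_displacement.tsv", disp_df, params)
        write_table(out / "interface_maxima.tsv", maxima_df, params)
        write_table(out / "interface_rmsd_fits.tsv", rmsd_df, params)
        write_table(out / "sasa_averages.tsv", sasa_df, params)
        manifest = {
            "parameters": params,
            "inputs": {
                "topology": {"path": str(config.topology), "sha256": _sha256(Path(config.topology))},
                "site_map": {"path": str(config.site_map), "sha256": _sha256(Path(config.site_map))},
                "trajectories": [
                    {"path": str(p), "sha256": _sha256(Path(p))} for p in config.trajectories
                ],
            },
            "summary": {
                "n_chain_replicates": summary.n_chain_replicates,
                "raw_event_count": summary.raw_event_count,
                "normalized_event_count": summary.normalized_event_count,
                "return_to_down_count": int(swing_df["returned_down"].sum()),
                "normalized_swing_times_ns": summary.normalized_swing_times,
                "mean_normalized_swing_time_ns": summary.mean_normalized_swing_time,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return ReportBundle(
        treatment=config.treatment,
        swing_records=swing_df,
        treatment_summary=summary,
        fe_l1_means=fe_l1_df,
        iron_displacement=disp_df,
        interface_maxima=maxima_df,
        interface_rmsd_fits=rmsd_df,
        sasa_averages=sasa_df,
        manifest=manifest,
    )


def compare_treatments(metric_by_treatment: dict[str, np.ndarray], metric: str = "",
                       units: str = "") -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD across treatments for one pooled metric."""
    from .stats import GroupedSamples, tukey_pairwise

    samples = GroupedSamples(groups=list(metric_by_treatment.items()),
                             metric=metric, units=units)
    result = tukey_pairwise(samples)
    rows = [{
        "comparison": "ANOVA", "pair": "all", "statistic": result.statistic,
        "df": f"{int(result.df[0])},{int(result.df[1])}", "p": result.p_value,
        "mean_difference": np.nan,
    }]
    for pw in result.pairwise:
        rows.append({
            "comparison": "Tukey HSD", "pair": f"{pw.pair[0]} vs {pw.pair[1]}",
            "statistic": pw.statistic, "df": "", "p": pw.adjusted_p,
            "mean_difference": pw.mean_difference,
        })
    return pd.DataFrame(rows)


def compare_crystal_structures(
    model_low: StructureModel,
    model_high: StructureModel,
    map_low: SiteMap,
    map_high: SiteMap,
) -> pd.DataFrame:
    """Single-frame Fe-L1 and iron-displacement comparison of two structures.

    Applies the trajectory operations to each structure as a one-frame
    trajectory, per alpha chain, and reports low-minus-high differences of
    the chain means (nm) — the T-state vs R-state heme-geometry contrast.
    """
    rows = []
    per_structure_means: dict[str, dict[str, float]] = {}
    for tag, model, site_map in (("low", model_low, map_low), ("high", model_high, map_high)):
        from .structure_io import Trajectory

        traj = Trajectory(times=np.array([0.0]), coordinates=model.positions[None, :, :])
        fe_l1_vals, disp_vals = [], []
        for chain in site_map.chains_of("alpha"):
            i_ne = resolve_site(model, site_map, "alpha", "F8", "NE2", chain_id=chain)
            heme = model.heme_for_chain(chain)
            d = geo.distance_trace(traj, i_ne, heme.fe_index, equilibration_cutoff=0.0)
            disp = geo.iron_plane_displacement(traj, heme.fe_index, heme.pyrrole_indices, i_ne,
                                               equilibration_cutoff=0.0)
            fe_l1_vals.append(d.values[0])
            disp_vals.append(disp.values[0])
            rows.append({"structure": tag, "chain": chain,
                         "fe_l1_nm": float(d.values[0]),
                         "iron_displacement_nm": float(disp.values[0])})
        per_structure_means[tag] = {
            "fe_l1_nm": float(np.mean(fe_l1_vals)),
            "iron_displacement_nm": float(np.mean(disp_vals)),
        }
    rows.append({
        "structure": "low-minus-high", "chain": "mean",
        "fe_l1_nm": per_structure_means["low"]["fe_l1_nm"] - per_structure_means["high"]["fe_l1_nm"],
        "iron_displacement_nm": (per_structure_means["low"]["iron_displacement_nm"]
                                 - per_structure_means["high"]["iron_displacement_nm"]),
    })
    return pd.DataFrame(rows)
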