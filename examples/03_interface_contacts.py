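"""alpha1-beta2 interface contacts on a synthetic replicate.

Generates a 2-replicate bovine-like system with a planted site-2 excursion
to 1.15 nm (the Arg beta2-C6 guanidinium swinging toward solvent), then
reports per-site maximum distances and the local backbone-RMSD drift.
"""

import tempfile
from pathlib import Path

from hemegate import read_trajectory
from hemegate.interface import (
    CANONICAL_SITES,
    interface_rmsd_slope,
    interface_selection,
    max_site_distance,
    site_distance_trace,
)
from hemegate.synthetic import (
    Site2Excursion,
    SyntheticSystemSpec,
    generate_synthetic_system,
)

spec = SyntheticSystemSpec(
    n_replicates=2, replicate_lengths_ns=(40.0, 36.0), swing_plan=(),
    site2_excursion=Site2Excursion(replicate_index=1, t_center_ns=18.0, peak_nm=1.15),
)
with tempfile.TemporaryDirectory() as tmp:
    system = generate_synthetic_system(Path(tmp), spec, seed=4)
    for r, rep in enumerate(system.replicates):
        traj = read_trajectory(system.model, rep.trajectory_path)
        print(f"{rep.replicate_id} ({rep.length_ns:.0f} ns):")
        for site in CANONICAL_SITES.values():
            trace = site_distance_trace(traj, system.model, system.site_map, site, "A", "D")
            print(f"  {site.report_label:8s} ({site.interaction_class:13s}) "
                  f"max = {max_site_distance(trace):.3f} nm")
        sel = interface_selection(system.model, system.site_map, "A", "D")
        slope, intercept, _ = interface_rmsd_slope(traj, sel, 0, t_start=1.0,
                                                   t_end=rep.length_ns)
        print(f"  interface backbone RMSD drift: {slope:.2e} nm/ns over {sel.n_atoms} atoms")
# Site 2' (the Thr alpha1-C6 hydrogen bond) exists only for bovine-like maps;
# a trout-like map raises a SiteApplicabilityError for it, leaving 3 sites.
# The rep2 site-2 maximum sits at the planted 1.15 nm excursion (+/- OU noise).
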