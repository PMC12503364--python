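"""Heme-pocket solvent accessibility: E11 SASA under a planted burial schedule.

An E11-like residue sits inside an occluder shell that opens along a linear
schedule; its Shrake-Rupley SASA must track the schedule monotonically.
"""

import numpy as np
from scipy.stats import spearmanr

from hemegate import SASAParams, residue_sasa_trace
from hemegate.synthetic import generate_e11_burial_series

schedule = np.linspace(0.0, 1.0, 30)
model, traj, site_map = generate_e11_burial_series(schedule)
trace = residue_sasa_trace(traj, model, site_map, "alpha", "A",
                           params=SASAParams(n_sphere_points=480),
                           equilibration_cutoff=0.0)

for k in (0, 7, 15, 22, 29):
    print(f"open fraction {schedule[k]:.2f} -> E11 SASA {trace.values[k]:.3f} nm^2")
rho = spearmanr(schedule, trace.values).statistic
print(f"\nSpearman rho(schedule, SASA) = {rho:.4f}")
print("0 nm^2 when fully buried; ~1.8 nm^2 (the isolated-residue value) when open.")
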