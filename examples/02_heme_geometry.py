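"""Heme geometry: Fe-L1 distance, iron out-of-plane displacement, stacking.

Builds a one-frame heme fragment with the iron displaced 0.04 nm toward the
proximal histidine, measures the displacement relative to the pyrrole-N
plane, and classifies two constructed aromatic ring pairs.
"""

import numpy as np

from hemegate import Trajectory, iron_plane_displacement, stacking_geometry

# Fe 0.04 nm above the square of pyrrole nitrogens; proximal His reference above
frame = np.array([
    [0.0, 0.0, 0.04],                                    # Fe
    [0.1, 0, 0], [0, 0.1, 0], [-0.1, 0, 0], [0, -0.1, 0],  # pyrrole N
    [0.0, 0.0, 0.25],                                    # proximal His Ne2
])
traj = Trajectory(times=np.array([0.0]), coordinates=frame[None])
disp = iron_plane_displacement(traj, 0, [1, 2, 3, 4], 5, equilibration_cutoff=0.0)
print(f"iron displacement: {disp.values[0]:+.3f} nm "
      "(positive = toward the proximal histidine, i.e. T-state-like doming)")

fe_l1 = np.linalg.norm(frame[0] - frame[5])
print(f"Fe-L1 distance:    {fe_l1:.3f} nm")


def ring(center, normal, radius=0.14):
    normal = np.asarray(normal, float) / np.linalg.norm(normal)
    a = np.cross(normal, [1.0, 0.3, 0.2]); a /= np.linalg.norm(a)
    b = np.cross(normal, a)
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    return np.asarray(center) + radius * (np.outer(np.cos(ang), a) + np.outer(np.sin(ang), b))


# an imidazole-over-aromatic pair like HisE7 against the CE4 side chain
for label, other in (("offset-stacked pair", ring([0.15, 0, 0.38], [0, 0, 1])),
                     ("perpendicular pair", ring([0, 0, 0.50], [1, 0, 0]))):
    g = stacking_geometry(ring([0, 0, 0], [0, 0, 1]), other)
    print(f"{label}: centroid {g.centroid_distance:.2f} A, angle {g.interplanar_angle:.0f} deg, "
          f"offset {g.offset:.2f} A -> {g.stacking_class}")
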