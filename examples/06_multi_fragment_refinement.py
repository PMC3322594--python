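"""Simultaneous multi-fragment refinement (collage).

Six monomers are displaced by up to 5 A / 10 deg from their true poses in
a simulated hexamer map, then refined *jointly* by Powell maximization of
the shared correlation.  Because the CC normalizes by the norm of the
summed fragment density, overlapping fragments score worse — the
normalization itself acts as a steric-clash penalty.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from minisitus import FragmentSet, RigidTransform, ScoreConfig, collage_refine
from minisitus.convert import Kernel
from minisitus.fixtures import make_hexamer_map
from minisitus.transforms import kabsch

fx = make_hexamer_map(seed=1)
rng = np.random.default_rng(42)
frags, truths = [], []
for rt in fx.transforms:
    truth = fx.monomer.transformed(rt)
    truths.append(truth)
    shift = rng.uniform(-1, 1, 3)
    shift *= rng.uniform(2, 5) / np.linalg.norm(shift)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.deg2rad(rng.uniform(4, 10)) * axis).as_matrix()
    frags.append(truth.transformed(RigidTransform.about_pivot(R, truth.centroid, shift)))

config = ScoreConfig(kernel=Kernel("gaussian", resolution=15.0))
refined, trace = collage_refine(fx.map, FragmentSet(frags), config, max_steps=60)

print("CC trace:", " -> ".join(f"{s:.4f}" for s in trace))
for k, (model, truth) in enumerate(zip(refined.posed_models(), truths)):
    dt = np.linalg.norm(model.centroid - truth.centroid)
    dr = kabsch(model.coords, truth.coords).rotation_angle_deg()
    print(f"fragment {k}: residual {dt:.3f} A, {dr:.3f} deg")
# All six fragments return to their planted poses well within 1 A / 2 deg,
# and the score trace is monotone non-decreasing (Powell never accepts a
# worse configuration).
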