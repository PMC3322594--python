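"""Feature-point docking: vector quantization + unequal-size matching.

Encodes the monomer as N=5 codebook vectors and the hexamer map as M=30
(one protomer's worth times six), then registers the small cloud into the
large one by anchor-triangle search.  At low resolution the point RMSD is
often more discriminating than the narrow range of CC values.
"""

import numpy as np

from minisitus import matchpt, vq
from minisitus.convert import Kernel
from minisitus.features import match_quality, units_to_m
from minisitus.fixtures import make_hexamer_map
from minisitus.transforms import rmsd

fx = make_hexamer_map(seed=1)
n = 5
m = units_to_m(n, units=6.0)  # six protomers fill the map volume
probe_cloud = vq(fx.monomer, n, seed=0)
target_cloud = vq(fx.map, m, seed=1)
print(f"probe: {n} feature points; target: {m} feature points")
print(f"probe variability {probe_cloud.variability.mean():.2f} A, "
      f"target {target_cloud.variability.mean():.2f} A")

results = matchpt(probe_cloud, target_cloud, max_results=5)
kernel = Kernel("gaussian", resolution=15.0)
for i, r in enumerate(results, 1):
    posed = r.transform.apply(fx.monomer.coords)
    truth_err = min(rmsd(posed, rt.apply(fx.monomer.coords))
                    for rt in fx.transforms)
    q = match_quality(r, probe_cloud, target_cloud, fx.map, fx.monomer, kernel)
    print(f"rank {i}: point RMSD {r.rmsd:5.2f} A, CC {q.cc_at_pose:.4f}, "
          f"error vs planted protomer {truth_err:5.2f} A")
# The best-RMSD match places the monomer on one of the six planted
# protomers to within the feature-point reproducibility (~1 A here).
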