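"""From MD-like snapshots to map frequencies: the two-population structure.

Generates frames of a linear alkyne probe whose amine-like donor cluster
alternates between facing the terminal hydrogen (associated) and sitting in
the bulk (free), extracts the six map variables per frame (projected DSF
electric field + derivatives, repulsive LJ sums), and evaluates the
published spectroscopic map.  Donor association produces a distinctly
red-shifted subpopulation.
"""

import numpy as np

from specmap import MapModel, compute_features, delta_omega_tea, omega_map
from specmap.synthetic import make_structured_frames

frames, occupied, params = make_structured_frames(n_frames=400, occupancy=0.55, seed=31)
model = MapModel.published()

features = np.array([compute_features(f).as_array() for f in frames])
shifts = delta_omega_tea(features, model)
omegas = omega_map(features, (180.0, 180.0), "PAC", model)

print(f"{len(frames)} frames, donor occupancy {occupied.mean():.2f}")
print(f"solvent shift, associated frames: {shifts[occupied].mean():+6.2f} "
      f"+/- {shifts[occupied].std():.2f} cm^-1")
print(f"solvent shift, free frames      : {shifts[~occupied].mean():+6.2f} "
      f"+/- {shifts[~occupied].std():.2f} cm^-1")
print(f"map frequency means             : {omegas[occupied].mean():.2f} (associated) "
      f"vs {omegas[~occupied].mean():.2f} (free) cm^-1")
# The associated population sits several cm^-1 below the free one -- the
# electron-rich nitrogen facing the terminal hydrogen lowers the stretch
# frequency, which is what makes the combined distribution bimodal.
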