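"""Model alveolar expansion from a boundary point cloud.

The alveolar inner boundary is reduced to a planar polygon at a fixed z:
its area A, perimeter P and ratio R = A/P (a length-scale index of shape
complexity, the opposite of compactness) are followed over time.
"""

import numpy as np

from alveo4d import alveolus as alv
from alveo4d import simulate as sim

# a control alveolus doubling its radius (10 -> 20 um) over ten snapshots
cloud = sim.alveolus_cloud(mode="control", r0=10.0, r1=20.0, seed=3)
series = alv.expansion_series(cloud, z_level=40.0)
print(series.round(2).to_string(index=False))
growth = series.A.iloc[-1] / series.A.iloc[0]
print(f"area growth {growth:.2f}x (a doubled radius gives 4x), "
      f"R grows {series.R.iloc[-1] / series.R.iloc[0]:.2f}x")

# a Wnt-perturbed alveolus: no expansion, flat series
wnt = alv.expansion_series(sim.alveolus_cloud(mode="wnt_inhibited", seed=3), 40.0)
wnt = wnt.dropna()
slope = np.polyfit(wnt.t, wnt.P, 1)[0] / wnt.P.mean()
print(f"wnt-perturbed relative perimeter slope: {slope:.2e} per h (flat)")
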