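"""Normalising growth maps to a common 90-day interval, then smoothing.

Growth parameters measured over different inter-scan intervals are not
comparable; the per-90-day adjustment rescales the deviation from the
no-growth value (JD = 1, strain = 0) by 90/days. One edge-preserving
smoothing pass then suppresses voxel noise without blurring region borders.
"""

import numpy as np

from strainmorph import ScalarMap, default_grid, interval_adjust, smooth_map

grid = default_grid(16, spacing=2.0)

# a JD map measured over a 180-day interval: 40% expansion in one half
jd = np.where(np.arange(16)[:, None, None] < 8, 1.0, 1.4) * np.ones(grid.shape)
jd_map = ScalarMap(grid, jd)

adjusted = interval_adjust(jd_map, days_between_scans=180, jd_mode="offset")
print("JD 1.4 over 180 days -> per-90-day JD:", adjusted.values.max())  # 1.2
print("null value JD = 1 is preserved:", adjusted.values.min())  # 1.0

smoothed = smooth_map(adjusted, iterations=1, kappa=0.1)
print("plateau values after smoothing:",
      round(smoothed.values[2, 8, 8], 4), round(smoothed.values[13, 8, 8], 4))
print("mean preserved:",
      np.isclose(smoothed.values.mean(), adjusted.values.mean(), atol=1e-9))

# The step between the two compartments survives the smoothing pass (edge
# preservation); only within-compartment noise would be diffused.
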