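"""Detect nuclei in a synthetic DAPI image and compute density metrics.

Places Gaussian nuclear spots in a disk with a chosen radial density
profile, detects them by bandpass + peak finding, and reports count, fold
change and the radial density profile.
"""

import numpy as np

import sheetflow as sf

params_t0 = sf.SyntheticParams(seed=2, sheet_radius0=120.0, pixel_size=1.0, noise_level=2.0)
params_t15 = sf.SyntheticParams(seed=8, sheet_radius0=120.0, pixel_size=1.0, noise_level=2.0)

stack0, truth = sf.generate_nuclei_image(params_t0, n_cells=100, image_shape=(300, 300), min_spacing=12)
stack1, _ = sf.generate_nuclei_image(params_t15, n_cells=200, image_shape=(300, 300), min_spacing=10)

det0 = sf.detect_nuclei(stack0.frames[0])
det1 = sf.detect_nuclei(stack1.frames[0])
fold, density, (centers, profile) = sf.density_metrics(det0, det1, truth.geometry, pixel_size=1.0)

print(f"nuclei at t=0 h      : {det0.count} detected of 100 placed")
print(f"nuclei at t=15 h     : {det1.count} detected of 200 placed")
print(f"fold change          : {fold:.2f} (t15/t0 counts; 2.0 = one doubling)")
print(f"average density      : {density * 1e6:.1f} cells/mm² inside the sheet")
inner = np.nanmean(profile[2:10]) * 1e6
print(f"radial profile       : inner-bin mean {inner:.1f} cells/mm² "
      "(flat for the uniform placement used here)")
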