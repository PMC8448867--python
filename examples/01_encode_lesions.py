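"""Encode lesion masks against an atlas as a lesion-load matrix.

Builds a small in-memory atlas (five slab regions) and three synthetic
lesion masks, then computes each patient's load (fraction of region voxels
lesioned) per region. Regions no lesion touches are pruned and reported.
"""

import numpy as np

import lesionpls as lp

shape = (8, 8, 10)
regions = []
for i in range(5):
    membership = np.zeros(shape, dtype=int)
    membership[:, :, 2 * i : 2 * i + 2] = 1  # five slabs along z
    regions.append(lp.Region(f"slab{i}", "demo-atlas", membership))
atlas = lp.RegionSet(tuple(regions), space_tag="demo")

rng = np.random.default_rng(0)
masks = []
for p in range(3):
    grid = np.zeros(shape, dtype=int)
    z0 = 2 * p  # each patient's lesion sits in a different part of the volume
    grid[2:6, 2:6, z0 : z0 + 4] = (rng.random((4, 4, 4)) < 0.7).astype(int)
    masks.append(lp.LesionMask(f"patient{p}", grid, space_tag="demo"))

loads = lp.encode_cohort(masks, atlas)
print(loads.to_dataframe().round(3))
print(f"\npruned (untouched) regions: {loads.dropped_region_ids}")
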