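"""Reference a significant-voxel map to a probabilistic tract atlas.

Fabricates two toy probabilistic tract maps, binarizes them at P >= 0.4 and
reports the overlap volume with a significance mask, omitting tracts under
the 20 mm^3 reporting floor.
"""

import numpy as np

from famap import TractAtlas, Volume, overlap_report

rng = np.random.default_rng(0)
shape = (20, 20, 20)

# significance mask: a 6x6x6 block (216 voxels = 216 mm^3 on a 1 mm grid)
sig = np.zeros(shape, dtype=np.int16)
sig[5:11, 5:11, 5:11] = 1

# tract A passes through the block with high probability; tract B barely
tract_a = np.zeros(shape)
tract_a[5:11, 5:11, :] = 0.8
tract_b = np.zeros(shape)
tract_b[9:11, 9:11, 8:12] = 0.45
tract_c = np.full(shape, 0.39)  # never survives the 0.4 cutoff

atlas = TractAtlas(
    maps={"arcuate-like": Volume(tract_a, np.eye(4)),
          "minor-bundle": Volume(tract_b, np.eye(4)),
          "subthreshold": Volume(tract_c, np.eye(4))},
    categories={"arcuate-like": "association",
                "minor-bundle": "association",
                "subthreshold": "projection"},
)

report = overlap_report(Volume(sig, np.eye(4)), atlas,
                        min_volume_mm3=20.0, threshold=0.4)
print(report.to_string(index=False))
# Interpretation: overlap is counted on maps binarized at P >= 0.4 (so the
# 0.39 map vanishes) and tracts with < 20 mm^3 of overlap are not reported.
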