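"""Total Cobb angle from vertebral landmark lines.

Each spinal curve is measured as the acute angle between lines drawn
parallel to the two most displaced vertebrae (equivalently, between their
perpendiculars); per fish, the angles of all curves in both views are
summed.
"""

import scoliomorph as sm
from scoliomorph.simulate import gen_vertebral_lines

true_angles = [12.0, 27.5, 41.0]  # three curves of one skeletal preparation
measurements = gen_vertebral_lines(true_angles, seed=4)

for m, truth in zip(measurements, true_angles):
    print(f"curve: measured {m.angle:.2f} deg (constructed at {truth:.1f} deg)")
print(f"total Cobb angle: {sm.total_cobb(measurements):.2f} deg (sum of all curves)")
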