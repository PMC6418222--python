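"""The convexity/size merge model on two contrasting fixtures.

An over-split disk (two jagged halves) should be rejoined: the union is
more convex than its fragments.  Two genuinely distinct touching disks
should stay separate: their union is a dumbbell, less convex than
either disk.
"""

import numpy as np

from nucleisplit import convexity, merge_objects
from nucleisplit.synthetic import _disk_mask

# a convex disk cut in two along a jagged line
shape = (28, 28)
disk = _disk_mask(shape, (13.5, 13.5), 11.0)
yy, xx = np.indices(shape)
R = np.zeros(shape, dtype=int)
R[disk & ((xx + yy % 2) < 14)] = 1
R[disk & ~((xx + yy % 2) < 14)] = 2
print(f"over-split disk: fragment convexities "
      f"{convexity(R == 1):.3f}, {convexity(R == 2):.3f}; "
      f"union {convexity(R > 0):.3f}")
print(f"  after merging: {merge_objects(R, omega_min=50).max()} object(s)")

# two real nuclei sharing a border
shape = (24, 44)
R2 = np.zeros(shape, dtype=int)
d1 = _disk_mask(shape, (12.0, 11.0), 9.0)
d2 = _disk_mask(shape, (12.0, 29.0), 9.0)
R2[d1] = 1
R2[d2 & ~d1] = 2
print(f"touching disks: convexities {convexity(R2 == 1):.3f}, "
      f"{convexity(R2 == 2):.3f}; union {convexity(R2 > 0):.3f}")
print(f"  after merging: {merge_objects(R2, omega_min=50).max()} object(s)")
print("a merge is accepted only when the union is more convex than the "
      "fragments on average and stays under 10 x omega_min in size.")
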