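"""Store a temporal sequence as a spatial primacy gradient.

Presents "1-2-3" and "3-2-1" to the two-layer working memory as 0.75-unit
input pulses and prints the stored activity pattern.  The earlier an item
arrived, the higher its final activity — ranking the activities recovers
the presented order, which is how the downstream categorization network can
read serial order from a static pattern.
"""

import numpy as np

from maskfield import SequenceSpec, ltm_invariance_ratio_error, run_wm

for text in ("1-2-3", "3-2-1"):
    seq = SequenceSpec.from_string(text)
    traj = run_wm(seq, m=3)
    x = traj.final_x
    order = "-".join(str(i + 1) for i in np.argsort(-x))
    drift = ltm_invariance_ratio_error(traj, seq)
    print(f"sequence {text}:  stored x = {np.round(x, 5)}")
    print(f"  order read from gradient: {order}   "
          f"(max ratio drift while storing: {drift:.2e})")

# The drift number is the largest relative change in the ratio of any two
# already-stored activities while a new item was being integrated; values
# near zero mean earlier memories kept their relative code (the property
# that protects previously learned categories).
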