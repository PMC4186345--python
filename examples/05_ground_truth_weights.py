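"""Ground-truth weights: what the adaptive filter should converge to.

For a chunk committed to a sequence, the learning law's fixed point is the
stored working-memory pattern normalized to sum 1.  This script prints the
target for two orderings of the same items — the point being that the
*same* item set in a different order yields a different target, which is
what lets order-sensitive categories exist at all.
"""

import numpy as np

from maskfield import SequenceSpec, ground_truth_weights

for text in ("1-2-3-4", "4-3-2-1"):
    target = ground_truth_weights(SequenceSpec.from_string(text), m=4)
    print(f"{text}: target weights = {np.round(target, 4)}")
# Each vector is a primacy gradient over the sequence's items: the first
# item carries the largest weight.  A chunk whose weights match one target
# responds more strongly to that ordering than to any other ordering of the
# same items.
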