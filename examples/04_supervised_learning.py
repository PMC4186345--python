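"""Supervised learning with mismatch reset.

With free random initial weights (no balancing) several sequences initially
select the same cell.  In supervised mode a cell that crosses the firing
threshold while already committed to a different sequence is reset — its
gate closes for the rest of the trial — and the search continues until an
admissible cell wins.  Across presentations the resets die out and
selection gets faster.
"""

import numpy as np
from scipy import stats

from maskfield import supervised_campaign

rep = supervised_campaign(m=4, cycles=60, seed=0)
n = rep.n_sequences
per_cycle = [sum(rep.reset_series[i * n:(i + 1) * n])
             for i in range(rep.cycles_run)]
print(f"uniquely committed:  {rep.n_uniquely_learned}/{n}")
print(f"cycles run:          {rep.cycles_run}")
print(f"resets per cycle:    {per_cycle}")

rhos = [stats.spearmanr(np.arange(len(t)), t).statistic
        for t in rep.selection_times.values()
        if len(t) >= 3 and len(set(t)) > 1]
print(f"mean selection-time rank trend: {np.mean(rhos):+.3f} "
       "(negative = faster selection on later presentations)")
# The reset column falling to zero means every sequence eventually selects
# its own committed chunk outright, before any wrongly committed rival
# reaches threshold.
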