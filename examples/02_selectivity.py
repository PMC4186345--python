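"""Size-selective categorization without learning.

Builds the 64-chunk field over four items with balanced initial weights,
presents the probe lists "1", "1-2", "1-2-3", "1-2-3-4", and prints which
cell wins.  A list of length L should select a chunk wired to exactly L
items: shorter familiar sublists must not capture longer lists, and large
cells must not fire on partial evidence.
"""

from maskfield import selectivity_experiment

report = selectivity_experiment(ms=(4,), redundancies=(1,))
for p in report.probes:
    print(f"probe {p.sequence!s:>8}: winner size {p.winner_size} "
          f"(selected at t = {p.selection_time:.2f})  "
          f"{'ok' if p.passed else 'WRONG SIZE'}")
print(f"\nall probes selected the matching size: {report.passed}")
# The single-item probe is the slowest: a lone 1-chunk integrates the least
# total bottom-up evidence, so it takes longest to reach the firing
# threshold.
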