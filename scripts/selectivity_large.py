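#!/usr/bin/env python
"""Size-selectivity replication on the large catalogs (m = 6..9).

The 6- and 7-item fields (516 and 1099 chunks) take minutes; the 8- and
9-item fields (2080 and 3609 chunks) take tens of minutes per probe because
the all-to-all inhibition grows quadratically.  Under the packaged parameter
set the 8- and 9-item probes of length four stall below the firing threshold
(see docs/methods.md, "Known limitations"); this script measures and reports
whatever happens rather than asserting success.

Usage:  python scripts/selectivity_large.py --m 6 --m 7 [--seed 0] [--out selectivity_large.json]
"""

import argparse
import json
import time
from pathlib import Path

from maskfield import MFParams, selectivity_experiment
from maskfield.integrate import IntegratorConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--m", action="append", type=int, default=None)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--budget", type=float, default=240.0,
                        help="per-trial time budget (simulation units)")
    parser.add_argument("--out", type=Path, default=Path("selectivity_large.json"))
    args = parser.parse_args()
    ms = tuple(args.m) if args.m else (6, 7, 8, 9)

    integ = IntegratorConfig(max_trial_time=args.budget)
    results = []
    for m in ms:
        t0 = time.time()
        report = selectivity_experiment(ms=(m,), mf_params=MFParams(),
                                        integ=integ, seed=args.seed)
        for p in report.probes:
            results.append({
                "m": p.m, "sequence": p.sequence,
                "winner_size": p.winner_size,
                "selection_time": p.selection_time,
                "passed": p.passed,
            })
        print(f"m={m}: passed={report.passed} ({time.time() - t0:.0f}s)")
    args.out.write_text(json.dumps(results, indent=2))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
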