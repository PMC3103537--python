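#!/usr/bin/env python
"""Simulate a labelled four-regime trap cohort and write CSV fixtures.

Generates ``n`` traps per firing regime (metronomic, random, bursting,
waiting) with parameters drawn from the documented per-regime ranges,
renders each as a noisy width trace, and writes events + traces + the
manifest under ``results/cohort/``.  Everything downstream (02-04) reads
these fixtures back from disk, exercising the full I/O chain.
"""

import argparse
from collections import Counter

from utrap.pipeline_io import write_cohort
from utrap.simulator import make_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-per-regime", type=int, default=3)
    ap.add_argument("--out", default="results/cohort")
    args = ap.parse_args()

    labels = ["metronomic", "random", "bursting", "waiting"]
    spec = [lab for lab in labels for _ in range(args.n_per_regime)]
    members = make_cohort(spec, seed=args.seed)
    manifest = write_cohort(members, args.out)

    counts = Counter(m.label for m in members)
    events = sum(len(m.seq) for m in members)
    print(f"wrote {len(members)} traps ({dict(counts)}) with {events} firings")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
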