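#!/usr/bin/env python
"""Step 2: multi-start fit of the 15 optimized parameters to monkey means.

Refits the model to the group-mean synthetic monkey data from step 1.
The full 1000-start fit takes a few hours on one core; pass a smaller
``--n-starts`` for a quick look.  Outputs: results/fit/fit_all_sets.json
(every terminal set with its SSR and the acceptance mask) and
results/fit/fit_summary.csv (rank-1, median, range and identifiability
label per parameter).
"""

import argparse
from pathlib import Path

from tfpi_tmdd.cli import main

ROOT = Path(__file__).resolve().parents[1]

parser = argparse.ArgumentParser()
parser.add_argument("--n-starts", type=int, default=1000)
parser.add_argument("--seed", type=int, default=20240101)
args = parser.parse_args()

main(
    [
        "fit",
        "--observations", str(ROOT / "results" / "data" / "monkey_means.csv"),
        "--out", str(ROOT / "results" / "fit"),
        "--bw", "3.5",
        "--n-starts", str(args.n_starts),
        "--seed", str(args.seed),
    ],
    standalone_mode=False,
)
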