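#!/usr/bin/env python
"""Step 1: generate the synthetic monkey and rabbit study tables.

The real animal concentration data are not publicly deposited, so the
pipeline runs on synthetic tables simulated from the monkey rank-1
parameter set (monkey study) and its rabbit-scaled version (rabbit study)
under the published study designs, with 15% log-normal noise and n=3
animals per group.  Outputs go to results/data/.
"""

from pathlib import Path

from tfpi_tmdd.cli import main

RESULTS = Path(__file__).resolve().parents[1] / "results" / "data"

for design in ("monkey", "rabbit"):
    main(
        [
            "generate",
            "--design", design,
            "--noise-cv", "0.15",
            "--n-animals", "3",
            "--seed", "20240101",
            "--out", str(RESULTS),
        ],
        standalone_mode=False,
    )
print(f"wrote observation tables to {RESULTS}")
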