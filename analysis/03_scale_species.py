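#!/usr/bin/env python
"""Step 3: allometric scaling of the monkey rank-1 set to rabbit and human.

Exponents: 0.75 on distributional clearance, -0.25 on first-order rate
constants, 1.0 on volumes; KD and k_on are conserved; the membrane-TFPI
baseline is set from each species' literature soluble baseline via the
monkey membrane/soluble ratio.  Outputs one JSON per species under
results/scaling/.
"""

from pathlib import Path

from tfpi_tmdd.cli import main

RESULTS = Path(__file__).resolve().parents[1] / "results" / "scaling"

for species in ("rabbit", "human"):
    main(
        [
            "scale",
            "--species", species,
            "--out", str(RESULTS / f"{species}.json"),
        ],
        standalone_mode=False,
    )
print(f"wrote scaled parameter sets to {RESULTS}")
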