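#!/usr/bin/env python
"""Generate the benchmark spontaneous-report database.

60 drugs x 40 target diseases over 24 quarters (2014Q1-2019Q4) at a baseline
of 0.25 reports per pair-quarter, with 30 planted drug-disease pairs whose
report rate is elevated 10x during the 8 quarters before a logged domestic
label revision.  Writes the four report tables plus the revision log and
ground truth under results/data/.
"""

import sys
from pathlib import Path

from pvlabel.pipeline import stage_simulate
from pvlabel.simulate import study_config

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = Path("results/data")


def main() -> None:
    cfg = study_config(seed=SEED)
    info = stage_simulate(cfg, OUT)
    print(f"seed {SEED}: wrote {OUT}/")
    for name, n in info["rows"].items():
        print(f"  {name}.csv: {n} rows")
    print(f"  planted positive pairs: {len(cfg.planted_pairs)}")


if __name__ == "__main__":
    main()
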