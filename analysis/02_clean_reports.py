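#!/usr/bin/env python
"""Apply the three exclusion rules to the raw report tables.

Removes records whose onset precedes the first dose of the suspected drug,
duplicate records sharing (case id, preferred term, onset date), and records
whose suspected drug is over-the-counter.  Writes cleaned tables to
results/cleaned/ and the per-rule counts to results/exclusions.json.
"""

from pathlib import Path

from pvlabel.pipeline import stage_clean


def main() -> None:
    info = stage_clean(
        Path("results/data"), Path("results/cleaned"), Path("results/exclusions.json")
    )
    ex = info["exclusions"]
    total = sum(ex.values())
    print(f"{info['cases_in']} cases in, {info['cases_out']} retained")
    print(f"records: {total} in")
    for rule in ("pre_admin_onset", "duplicate", "otc"):
        print(f"  excluded by {rule}: {ex[rule]}")
    print(f"  retained: {ex['retained']}")


if __name__ == "__main__":
    main()
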