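#!/usr/bin/env python
"""Build the labeled drug-disease cohort from the cleaned reports.

Positives: pairs revised for domestic case accumulation, with features cut
off two quarters before the announcement.  Negatives: pairs reported during
the period but absent from the label at period end; their cut-off quarters
are matched to the positives' so observation-window length cannot act as a
label surrogate.  Writes results/cohort.csv.
"""

from pathlib import Path

from pvlabel.pipeline import stage_cohort


def main() -> None:
    info = stage_cohort(
        Path("results/cleaned"),
        Path("results/data/revisions.csv"),
        Path("results/data/listed.csv"),
        ("2014Q1", "2019Q4"),
        Path("results/cohort.csv"),
        negative_as_of="matched",
    )
    print(f"positives: {info['positives']}")
    print(f"negatives: {info['negatives']}")
    print(f"revisions excluded from labeling: {info['excluded_revisions']}")


if __name__ == "__main__":
    main()
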