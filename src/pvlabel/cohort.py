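"""Building the labeled drug-disease pair cohort.

Positives are pairs whose label gained the target disease because of
accumulated *domestic* case reports; since a revision is announced weeks to
months after the underlying risk investigation starts, a positive pair's
feature cut-off ("as-of" quarter) is placed two quarters before the
announcement.  Negatives are pairs for which the target disease was reported
during the analysis period but was still absent from the drug's label at the
period end; their as-of quarter is the final quarter of the period.

Pairs revised for a non-domestic reason belong to neither class, and
revisions whose disease name has no preferred-term grouping are excluded
with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .grouping import GroupingMap
from .quarters import Quarter
from .report_store import ReportCase
from .simulate import RevisionRecord

logger = logging.getLogger(__name__)

REVISION_REASONS = ("domestic", "domestic_and_overseas", "overseas", "other")


@dataclass(frozen=True)
class LabeledPair:
    drug: str
    disease: str
    label: str  # "positive" | "negative"
    as_of_quarter: Quarter
    source: str = ""


@dataclass
class CohortResult:
    pairs: list[LabeledPair]
    excluded_revisions: list[tuple[RevisionRecord, str]]

    @property
    def positives(self) -> list[LabeledPair]:
        return [p for p in self.pairs if p.label == "positive"]

    @property
    def negatives(self) -> list[LabeledPair]:
        return [p for p in self.pairs if p.label == "negative"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.drug, p.disease, p.label, str(p.as_of_quarter), p.source) for p in self.pairs],
            columns=["drug", "disease", "label", "as_of", "source"],
        )


def load_revisions(path: "str | Path") -> list[RevisionRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["drug", "disease", "quarter", "reason"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: revisions file missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        reason = str(row.reason).strip()
        if reason not in REVISION_REASONS:
            raise ValueError(f"{path}, row {i}: unknown revision reason {reason!r}")
        Quarter.parse(row.quarter)  # validate early
        records.append(RevisionRecord(str(row.drug), str(row.disease), str(row.quarter), reason))
    return records


def load_listed(path: "str | Path") -> set[tuple[str, str]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if not {"drug", "disease"} <= set(df.columns):
        raise ValueError(f"{path}: listed-pairs file needs columns drug, disease")
    return {(str(r.drug), str(r.disease)) for r in df.itertuples(index=False)}


def build_cohort(
    cases: Iterable[ReportCase],
    revisions: Iterable[RevisionRecord],
    listed_pairs: set[tuple[str, str]],
    gmap: GroupingMap,
    period: "tuple[str | Quarter, str | Quarter]",
    lag_quarters: int = 2,
    negative_as_of: str = "period_end",
) -> CohortResult:
    """Label drug-disease pairs from cleaned reports and the revision log.

    `listed_pairs` is the set of pairs whose disease already appears in the
    drug's label at the period end (this includes pairs revised during the
    period).  `period` is the inclusive (start, end) analysis window.

    ``negative_as_of`` controls the negatives' feature cut-off.  The default
    ``"period_end"`` uses the final quarter of the analysis window.
    ``"matched"`` instead recycles the positives' as-of quarters over the
    (sorted) negatives, so both classes see identically distributed
    observation windows; benchmarks use this to keep window length from
    acting as a label surrogate.
    """
    if negative_as_of not in ("period_end", "matched"):
        raise ValueError(f"unknown negative_as_of mode {negative_as_of!r}")
    start, end = Quarter.parse(period[0]), Quarter.parse(period[1])
    if end < start:
        raise ValueError(f"analysis period end {end} precedes start {start}")

    positives: dict[tuple[str, str], LabeledPair] = {}
    nonpositive_revised: set[tuple[str, str]] = set()
    excluded: list[tuple[RevisionRecord, str]] = []
    for rev in revisions:
        announce = Quarter.parse(rev.announce_quarter)
        pair = (rev.drug_code, rev.disease)
        if not start <= announce <= end:
            excluded.append((rev, "announced outside the analysis period"))
            nonpositive_revised.add(pair)
            continue
        if rev.disease not in gmap:
            excluded.append((rev, "disease not matchable to the PT grouping"))
            logger.warning(
                "revision for pair %s excluded: disease %r has no PT grouping",
                pair, rev.disease,
            )
            nonpositive_revised.add(pair)
            continue
        if rev.reason != "domestic":
            excluded.append((rev, f"revision reason {rev.reason!r} is not domestic"))
            nonpositive_revised.add(pair)
            continue
        if pair not in positives:
            positives[pair] = LabeledPair(
                drug=rev.drug_code,
                disease=rev.disease,
                label="positive",
                as_of_quarter=announce - lag_quarters,
                source=f"domestic revision announced {announce}",
            )

    # reported-but-unlisted pairs within the period
    reported: set[tuple[str, str]] = set()
    for case in cases:
        if not start <= case.quarter_received <= end:
            continue
        diseases = {gmap.map_pt(r.pt_name) for r in case.reactions}
        diseases.discard(None)
        for entry in case.suspected():
            for disease in diseases:
                reported.add((entry.drug_code, disease))

    pos_cutoffs = sorted(p.as_of_quarter for p in positives.values())
    negatives = []
    i = 0
    for pair in sorted(reported):
        if pair in positives or pair in listed_pairs or pair in nonpositive_revised:
            continue
        if negative_as_of == "matched" and pos_cutoffs:
            cutoff = pos_cutoffs[i % len(pos_cutoffs)]
            source = f"reported but unlisted; as-of matched to positive rank {i % len(pos_cutoffs)}"
        else:
            cutoff = end
            source = "reported but unlisted at period end"
        i += 1
        negatives.append(
            LabeledPair(
                drug=pair[0],
                disease=pair[1],
                label="negative",
                as_of_quarter=cutoff,
                source=source,
            )
        )

    pairs = sorted(
        list(positives.values()) + negatives,
        key=lambda p: (p.label != "positive", p.drug, p.disease),
    )
    return CohortResult(pairs=pairs, excluded_revisions=excluded)
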