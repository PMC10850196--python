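"""Disproportionality statistics over drug-disease 2x2 contingency tables.

For a drug of interest and a target disease, unique patients (cases) are
cross-classified as of a cut-off quarter:

    a: target-disease patients on the suspected drug
    b: target-disease patients on all other drugs
    c: other-reaction patients on the suspected drug
    d: other-reaction patients on all other drugs

From these the package computes the reporting odds ratio (ROR = ad/bc), the
proportional reporting ratio (PRR = a(b+d) / (b(a+c))), Pearson's chi-squared
statistic with Yates' continuity correction, and two coverage percentages:

    Index A = 100 a / (a + c)   share of the drug's reports that are the target
    Index B = 100 a / (a + b)   share of the target's reports that are the drug

Confidence intervals use the standard log-scale Wald forms
(ROR: exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d));
PRR:  exp(ln PRR +/- z * sqrt(1/a - 1/(a+c) + 1/b - 1/(b+d)))).
Zero denominators yield NaN ("undefined") rather than exceptions; an optional
Haldane correction (+0.5 to every cell) is available but off by default since
the plain ratio definitions carry no correction.

The conventional screening rule flags a pair as a signal when the cumulative
report count, the Yates chi-squared and the PRR all clear their thresholds
(defaults n >= 3, chi2 >= 4, PRR >= 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .grouping import GroupingMap
from .quarters import Quarter
from .report_store import ReportCase

UNDEFINED = float("nan")

Z_95 = 1.959964  # two-sided 95% normal quantile


def is_defined(x: float) -> bool:
    return x == x  # NaN-safe


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def with_haldane(self) -> "tuple[float, float, float, float]":
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class StatResult:
    value: float
    log_value: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def _wald(value: float, se: float, level: float) -> StatResult:
    if not is_defined(value) or value <= 0 or not is_defined(se):
        log_v = math.log(value) if is_defined(value) and value > 0 else UNDEFINED
        return StatResult(value, log_v, UNDEFINED, UNDEFINED, level)
    log_v = math.log(value)
    z = Z_95 if level == 0.95 else _z(level)
    return StatResult(value, log_v, math.exp(log_v - z * se), math.exp(log_v + z * se), level)


def _z(level: float) -> float:
    # inverse normal CDF via Acklam-style rational approximation; only needed
    # for non-default confidence levels.
    from statistics import NormalDist

    return NormalDist().inv_cdf(0.5 + level / 2)


def ror(t: ContingencyTable, haldane: bool = False, level: float = 0.95) -> StatResult:
    """Reporting odds ratio ad/bc with a log-scale Wald interval."""
    a, b, c, d = (t.with_haldane() if haldane else (t.a, t.b, t.c, t.d))
    if b * c == 0 or a * d == 0:
        value = UNDEFINED if b * c == 0 else 0.0
        return StatResult(value, UNDEFINED, UNDEFINED, UNDEFINED, level)
    value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return _wald(value, se, level)


def prr(t: ContingencyTable, haldane: bool = False, level: float = 0.95) -> StatResult:
    """Proportional reporting ratio a(b+d)/(b(a+c)) with a Wald interval."""
    a, b, c, d = (t.with_haldane() if haldane else (t.a, t.b, t.c, t.d))
    if b == 0 or a + c == 0:
        return StatResult(UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED, level)
    if a == 0:
        return StatResult(0.0, UNDEFINED, UNDEFINED, UNDEFINED, level)
    value = (a * (b + d)) / (b * (a + c))
    var = 1 / a - 1 / (a + c) + 1 / b - 1 / (b + d)
    se = math.sqrt(var) if var > 0 else UNDEFINED
    return _wald(value, se, level)


def yates_chisq(t: ContingencyTable) -> float:
    """Pearson chi-squared with Yates' continuity correction, floored at 0.

    Undefined (NaN) when any table margin is zero.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return UNDEFINED
    diff = abs(a * d - b * c) - n / 2
    if diff <= 0:
        return 0.0
    return n * diff * diff / denom


def index_ab(t: ContingencyTable) -> tuple[float, float]:
    """(Index A, Index B) percentages; NaN where the denominator is zero."""
    a = t.a
    index_a = 100.0 * a / (a + t.c) if a + t.c > 0 else UNDEFINED
    index_b = 100.0 * a / (a + t.b) if a + t.b > 0 else UNDEFINED
    return index_a, index_b


@dataclass(frozen=True)
class SignalDecision:
    drug: str
    disease: str
    n_reports: int
    chisq: float
    prr: float
    detected: bool


def apply_signal_rule(
    t: ContingencyTable,
    drug: str = "",
    disease: str = "",
    n_min: int = 3,
    chi_min: float = 4.0,
    prr_min: float = 2.0,
) -> SignalDecision:
    """Conventional screening rule; an undefined statistic fails its threshold."""
    chi = yates_chisq(t)
    p = prr(t).value
    detected = (
        t.a >= n_min
        and is_defined(chi)
        and chi >= chi_min
        and is_defined(p)
        and p >= prr_min
    )
    return SignalDecision(drug, disease, t.a, chi, p, detected)


# ---------------------------------------------------------------------------
# tabulation from cleaned reports


def contingency_from_reports(
    cases: Iterable[ReportCase],
    drug: str,
    disease: str,
    gmap: GroupingMap,
    as_of: "str | Quarter",
) -> ContingencyTable:
    """2x2 table for (drug, disease) from reports received by `as_of`.

    Counts unique cases; only suspected-role drug entries qualify a case as
    exposed, and cases without any suspected drug are not tabulated.
    """
    if disease not in gmap:
        raise KeyError(f"disease {disease!r} not present in the grouping map")
    cutoff = Quarter.parse(as_of)
    a = b = c = d = 0
    for case in cases:
        if case.quarter_received > cutoff:
            continue
        suspected = case.suspected()
        if not suspected:
            continue
        on_drug = any(e.drug_code == drug for e in suspected)
        has_target = any(gmap.map_pt(r.pt_name) == disease for r in case.reactions)
        if on_drug and has_target:
            a += 1
        elif has_target:
            b += 1
        elif on_drug:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def observed_pairs(
    cases: Iterable[ReportCase], gmap: GroupingMap
) -> set[tuple[str, str]]:
    """All (suspected drug, mapped disease) pairs with at least one report."""
    pairs: set[tuple[str, str]] = set()
    for case in cases:
        diseases = {gmap.map_pt(r.pt_name) for r in case.reactions}
        diseases.discard(None)
        for entry in case.suspected():
            for dis in diseases:
                pairs.add((entry.drug_code, dis))
    return pairs


def signal_table(
    cases: "list[ReportCase]",
    gmap: GroupingMap,
    as_of: "str | Quarter",
    n_min: int = 3,
    chi_min: float = 4.0,
    prr_min: float = 2.0,
) -> pd.DataFrame:
    """Apply the screening rule to every observed drug-disease pair.

    Uses a single pass to index cases by drug and disease, then per-pair set
    arithmetic, which agrees with `contingency_from_reports` case by case.
    """
    cutoff = Quarter.parse(as_of)
    eligible = [c for c in cases if c.quarter_received <= cutoff and c.suspected()]
    drug_cases: dict[str, set[int]] = {}
    disease_cases: dict[str, set[int]] = {}
    for i, case in enumerate(eligible):
        for entry in case.suspected():
            drug_cases.setdefault(entry.drug_code, set()).add(i)
        for r in case.reactions:
            dis = gmap.map_pt(r.pt_name)
            if dis is not None:
                disease_cases.setdefault(dis, set()).add(i)
    total = len(eligible)
    rows = []
    for drug in sorted(drug_cases):
        dset = drug_cases[drug]
        for disease in sorted(disease_cases):
            sset = disease_cases[disease]
            a = len(dset & sset)
            if a == 0:
                continue
            b = len(sset) - a
            c = len(dset) - a
            t = ContingencyTable(a, b, c, total - a - b - c)
            dec = apply_signal_rule(t, drug, disease, n_min, chi_min, prr_min)
            rows.append(
                (drug, disease, t.a, t.b, t.c, t.d, dec.chisq, dec.prr, dec.detected)
            )
    return pd.DataFrame(
        rows, columns=["drug", "disease", "a", "b", "c", "d", "chisq", "prr", "detected"]
    )


# ---------------------------------------------------------------------------
# detections vs. label revisions


def crosstab_from_cells(
    detected_revised: int,
    detected_not_revised: int,
    missed_revised: int,
    neither: int,
) -> dict:
    """Summary of the detected x revised 2x2.

    Returns the four cells, the percentage of detected pairs that were in
    fact revised (rounded to the nearest integer, as conventionally printed)
    and the percentage of revised pairs the rule missed (one decimal).
    """
    n_detected = detected_revised + detected_not_revised
    n_revised = detected_revised + missed_revised
    pct_detected_revised = (
        round(100.0 * detected_revised / n_detected) if n_detected else UNDEFINED
    )
    pct_revised_missed = (
        round(100.0 * missed_revised / n_revised, 1) if n_revised else UNDEFINED
    )
    return {
        "detected_revised": detected_revised,
        "detected_not_revised": detected_not_revised,
        "missed_revised": missed_revised,
        "neither": neither,
        "pct_detected_revised": pct_detected_revised,
        "pct_revised_missed": pct_revised_missed,
    }


def crosstab_vs_revisions(
    decisions: Iterable[SignalDecision],
    revised_pairs: "set[tuple[str, str]] | Mapping[tuple[str, str], bool]",
) -> dict:
    """Cross-tabulate signal decisions against the revised-pair set.

    `revised_pairs` is either the set of (drug, disease) pairs whose label
    was revised (all other decided pairs are treated as not revised), or a
    mapping pair -> bool; with a mapping, a decided pair missing from it is
    an error.
    """
    cells = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    seen: set[tuple[str, str]] = set()
    is_mapping = isinstance(revised_pairs, Mapping)
    for dec in decisions:
        pair = (dec.drug, dec.disease)
        seen.add(pair)
        if is_mapping:
            if pair not in revised_pairs:
                raise KeyError(f"pair {pair!r} has no known revision status")
            revised = bool(revised_pairs[pair])
        else:
            revised = pair in revised_pairs
        cells[(dec.detected, revised)] += 1
    # revised pairs never decided at all still count as missed
    if not is_mapping:
        for pair in set(revised_pairs) - seen:
            cells[(False, True)] += 1
    return crosstab_from_cells(
        cells[(True, True)], cells[(True, False)], cells[(False, True)], cells[(False, False)]
    )
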