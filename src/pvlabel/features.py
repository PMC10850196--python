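"""The 34 per-pair features and their pre-processing.

For each labeled (drug, disease) pair, features are computed from reports
received **on or before the pair's as-of quarter** — never later, so nothing
that happens after the cut-off can leak into the prediction.  Only
suspected-role drug entries are tabulated.  The feature groups are:

* cumulative patient counts: patients, deaths, rechallenge patients,
  patients who discontinued the suspected drug;
* time-to-onset: mean and median days from first dose to reaction onset, and
  patients with onset within 15 / 30 / 90 days;
* per-case report quality: mean missing values per case, mean follow-up
  reports to the authority per case;
* coverage percentages Index A and Index B;
* reporting history: quarters elapsed since the first report (inclusive of
  both endpoints), newly reported patients in each of the last four single
  quarters, newly reported deaths / rechallenges / discontinuations /
  short-onset patients in the last quarter, and mean patients per quarter;
* disproportionality: PRR, log PRR and its 95% CI, Yates chi-squared, ROR,
  log ROR and its 95% CI, from the as-of contingency table.

Missing time-to-onset summaries are imputed from the median onset time of
the same disease under *other* drugs; disproportionality values that are
undefined at small counts are imputed neutrally (ratio 1, log 0) with a flag
column.  Standardization and quantile transforms are fitted on training data
only and frozen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import mean, median
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import disproportionality as dis
from .cohort import LabeledPair
from .grouping import GroupingMap
from .quarters import Quarter
from .report_store import ReportCase

logger = logging.getLogger(__name__)

#: the per-case fields whose emptiness counts toward "missing values per case"
MISSINGNESS_FIELDS = (
    "sex", "age_band", "weight_band", "onset_date", "start_date", "outcome", "history",
)

FEATURE_NAMES: tuple[str, ...] = (
    "n_patients",
    "n_deaths",
    "n_rechallenge",
    "n_discontinued",
    "onset_days_mean",
    "onset_days_median",
    "n_onset_within_15",
    "n_onset_within_30",
    "n_onset_within_90",
    "missing_per_case",
    "reports_per_case",
    "index_a",
    "index_b",
    "quarters_since_first",
    "new_patients_q1",
    "new_patients_q2",
    "new_patients_q3",
    "new_patients_q4",
    "new_deaths_q1",
    "new_rechallenge_q1",
    "new_discontinued_q1",
    "new_onset_within_15_q1",
    "new_onset_within_30_q1",
    "new_onset_within_90_q1",
    "patients_per_quarter",
    "prr",
    "log_prr",
    "prr_ci_low",
    "prr_ci_high",
    "yates_chisq",
    "ror",
    "log_ror",
    "ror_ci_low",
    "ror_ci_high",
)

NAN = float("nan")


@dataclass
class _CaseView:
    """Flattened per-case view used by the feature tabulations."""

    case_id: str
    qidx: int
    version: int
    missing_count: int
    suspected_drugs: frozenset
    # per (drug, disease): onset days (min over matching reactions), or None
    # populated lazily by CaseIndex helpers
    case: ReportCase


class CaseIndex:
    """One-pass index over cleaned cases for per-pair feature extraction."""

    def __init__(self, cases: Iterable[ReportCase], gmap: GroupingMap):
        self.gmap = gmap
        self.views: list[_CaseView] = []
        self.drug_cases: dict[str, set[int]] = {}
        self.disease_cases: dict[str, set[int]] = {}
        # (disease) -> list of (drug frozenset, days) for imputation donors
        self.disease_onsets: dict[str, list[tuple[frozenset, float]]] = {}
        for case in sorted(cases, key=lambda c: c.case_id):
            suspected = case.suspected()
            if not suspected:
                continue
            i = len(self.views)
            missing = 0
            if not case.sex:
                missing += 1
            if not case.age_band:
                missing += 1
            if not case.weight_band:
                missing += 1
            if all(r.onset_date is None for r in case.reactions):
                missing += 1
            if all(d.start_date is None for d in suspected):
                missing += 1
            if all(r.outcome in ("", "unknown") for r in case.reactions):
                missing += 1
            if not case.history:
                missing += 1
            drugs = frozenset(d.drug_code for d in suspected)
            self.views.append(
                _CaseView(case.case_id, case.quarter_received.index, case.version,
                          missing, drugs, case)
            )
            for code in drugs:
                self.drug_cases.setdefault(code, set()).add(i)
            diseases = set()
            for r in case.reactions:
                disease = gmap.map_pt(r.pt_name)
                if disease is not None:
                    diseases.add(disease)
            for disease in diseases:
                self.disease_cases.setdefault(disease, set()).add(i)
        self.quarter_indices = np.array(sorted(v.qidx for v in self.views), dtype=int)
        self._onset_cache: dict[tuple[int, str, str], Optional[float]] = {}

    def n_cases_through(self, qidx: int) -> int:
        return int(np.searchsorted(self.quarter_indices, qidx, side="right"))

    def pair_case_ids(self, drug: str, disease: str) -> set[int]:
        return self.drug_cases.get(drug, set()) & self.disease_cases.get(disease, set())

    def onset_days(self, i: int, drug: str, disease: str) -> Optional[float]:
        """Days from the drug's first dose to the earliest matching onset."""
        key = (i, drug, disease)
        if key in self._onset_cache:
            return self._onset_cache[key]
        case = self.views[i].case
        starts = [
            d.start_date for d in case.suspected()
            if d.drug_code == drug and d.start_date is not None
        ]
        days: Optional[float] = None
        if starts:
            start = min(starts)
            for r in case.reactions:
                if r.onset_date is None or self.gmap.map_pt(r.pt_name) != disease:
                    continue
                delta = (r.onset_date - start).days
                if days is None or delta < days:
                    days = float(delta)
        self._onset_cache[key] = days
        return days

    def case_flags(self, i: int, drug: str, disease: str) -> tuple[bool, bool, bool]:
        """(death, rechallenge, discontinued) for the pair within case i."""
        case = self.views[i].case
        death = any(
            r.outcome == "death" and self.gmap.map_pt(r.pt_name) == disease
            for r in case.reactions
        )
        entries = [d for d in case.suspected() if d.drug_code == drug]
        rechallenge = any(d.rechallenge == "readministered" for d in entries)
        discontinued = any(d.action == "discontinued" for d in entries)
        return death, rechallenge, discontinued

    def contingency(self, drug: str, disease: str, as_of: Quarter) -> dis.ContingencyTable:
        cutoff = as_of.index
        dset = {i for i in self.drug_cases.get(drug, set()) if self.views[i].qidx <= cutoff}
        sset = {i for i in self.disease_cases.get(disease, set()) if self.views[i].qidx <= cutoff}
        a = len(dset & sset)
        b = len(sset) - a
        c = len(dset) - a
        total = self.n_cases_through(cutoff)
        return dis.ContingencyTable(a, b, c, total - a - b - c)


def compute_features(
    pair: LabeledPair,
    index: CaseIndex,
) -> dict[str, float]:
    """The 34-feature vector for one labeled pair at its as-of quarter."""
    as_of = pair.as_of_quarter
    cutoff = as_of.index
    sel = [i for i in index.pair_case_ids(pair.drug, pair.disease)
           if index.views[i].qidx <= cutoff]
    sel.sort(key=lambda i: index.views[i].case_id)

    out: dict[str, float] = {name: 0.0 for name in FEATURE_NAMES}
    out["n_patients"] = float(len(sel))

    days_list: list[float] = []
    per_case: list[tuple[int, bool, bool, bool, Optional[float]]] = []
    for i in sel:
        death, rechal, disc = index.case_flags(i, pair.drug, pair.disease)
        days = index.onset_days(i, pair.drug, pair.disease)
        per_case.append((i, death, rechal, disc, days))
        if days is not None:
            days_list.append(days)
        out["n_deaths"] += death
        out["n_rechallenge"] += rechal
        out["n_discontinued"] += disc
        out["n_onset_within_15"] += days is not None and days <= 15
        out["n_onset_within_30"] += days is not None and days <= 30
        out["n_onset_within_90"] += days is not None and days <= 90

    out["onset_days_mean"] = mean(days_list) if days_list else NAN
    out["onset_days_median"] = median(days_list) if days_list else NAN
    out["missing_per_case"] = (
        mean(index.views[i].missing_count for i in sel) if sel else 0.0
    )
    out["reports_per_case"] = mean(index.views[i].version for i in sel) if sel else 0.0

    if sel:
        first_q = min(index.views[i].qidx for i in sel)
        qsf = cutoff - first_q + 1
        out["quarters_since_first"] = float(qsf)
        out["patients_per_quarter"] = len(sel) / qsf
        for k in range(1, 5):
            window = cutoff - (k - 1)
            out[f"new_patients_q{k}"] = float(
                sum(1 for i in sel if index.views[i].qidx == window)
            )
        last = [(i, de, re, di, da) for (i, de, re, di, da) in per_case
                if index.views[i].qidx == cutoff]
        out["new_deaths_q1"] = float(sum(de for _, de, _, _, _ in last))
        out["new_rechallenge_q1"] = float(sum(re for _, _, re, _, _ in last))
        out["new_discontinued_q1"] = float(sum(di for _, _, _, di, _ in last))
        out["new_onset_within_15_q1"] = float(
            sum(1 for _, _, _, _, da in last if da is not None and da <= 15))
        out["new_onset_within_30_q1"] = float(
            sum(1 for _, _, _, _, da in last if da is not None and da <= 30))
        out["new_onset_within_90_q1"] = float(
            sum(1 for _, _, _, _, da in last if da is not None and da <= 90))

    t = index.contingency(pair.drug, pair.disease, as_of)
    p = dis.prr(t)
    r = dis.ror(t)
    ia, ib = dis.index_ab(t)
    out["index_a"], out["index_b"] = ia, ib
    out["prr"], out["log_prr"] = p.value, p.log_value
    out["prr_ci_low"], out["prr_ci_high"] = p.ci_low, p.ci_high
    out["yates_chisq"] = dis.yates_chisq(t)
    out["ror"], out["log_ror"] = r.value, r.log_value
    out["ror_ci_low"], out["ror_ci_high"] = r.ci_low, r.ci_high
    return out


def compute_feature_table(
    pairs: Iterable[LabeledPair],
    cases: "list[ReportCase] | CaseIndex",
    gmap: Optional[GroupingMap] = None,
) -> pd.DataFrame:
    """Feature matrix for a cohort: one row per pair, 34 feature columns
    plus drug / disease / label / as_of."""
    if isinstance(cases, CaseIndex):
        index = cases
    else:
        if gmap is None:
            raise ValueError("gmap is required when passing raw cases")
        index = CaseIndex(cases, gmap)
    rows = []
    meta = []
    for pair in pairs:
        rows.append(compute_features(pair, index))
        meta.append((pair.drug, pair.disease, pair.label, str(pair.as_of_quarter)))
    features = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    head = pd.DataFrame(meta, columns=["drug", "disease", "label", "as_of"])
    return pd.concat([head, features], axis=1)


def impute_onset_days(table: pd.DataFrame, index: CaseIndex) -> pd.DataFrame:
    """Fill missing onset mean/median from other drugs' same-disease median.

    For a pair with no observed time-to-onset, the donor value is the median
    of onset days for the same disease across all *other* drugs' cases (all
    report quarters).  Pairs with no donor anywhere keep NaN and are logged.
    A boolean ``onset_imputed`` column records which rows were filled.
    """
    table = table.copy()
    # donor pool: per disease, (drug-set, days) over every case
    pool: dict[str, list[tuple[frozenset, float]]] = {}
    for disease, case_ids in index.disease_cases.items():
        entries = []
        for i in case_ids:
            view = index.views[i]
            for drug in sorted(view.suspected_drugs):
                days = index.onset_days(i, drug, disease)
                if days is not None:
                    entries.append((view.suspected_drugs, days))
                    break
        pool[disease] = entries

    imputed = np.zeros(len(table), dtype=bool)
    for pos, row in enumerate(table.itertuples(index=False)):
        if not (math.isnan(row.onset_days_mean) or math.isnan(row.onset_days_median)):
            continue
        donors = [
            days for drugs, days in pool.get(row.disease, [])
            if row.drug not in drugs
        ]
        if not donors:
            logger.warning(
                "no donor onset data for disease %r; pair (%s, %s) keeps missing onset",
                row.disease, row.drug, row.disease,
            )
            continue
        value = float(median(donors))
        table.iloc[pos, table.columns.get_loc("onset_days_mean")] = value
        table.iloc[pos, table.columns.get_loc("onset_days_median")] = value
        imputed[pos] = True
    table["onset_imputed"] = imputed
    return table


#: neutral fill-ins for disproportionality values undefined at small counts
_DISPRO_NEUTRAL = {
    "prr": 1.0, "log_prr": 0.0, "prr_ci_low": 1.0, "prr_ci_high": 1.0,
    "ror": 1.0, "log_ror": 0.0, "ror_ci_low": 1.0, "ror_ci_high": 1.0,
    "yates_chisq": 0.0, "index_a": 0.0, "index_b": 0.0,
}


def finalize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Resolve remaining NaNs so the matrix is model-ready.

    Undefined disproportionality statistics become neutral values (ratio 1,
    i.e. 0 on the log scale; chi-squared and coverage percentages 0) with a
    ``dispro_imputed`` flag; onset summaries that found no donor become 0
    with the existing ``onset_imputed`` flag left False.
    """
    table = table.copy()
    dispro_cols = list(_DISPRO_NEUTRAL)
    flag = table[dispro_cols].isna().any(axis=1)
    for col, value in _DISPRO_NEUTRAL.items():
        table[col] = table[col].fillna(value)
    table["dispro_imputed"] = flag.to_numpy()
    for col in ("onset_days_mean", "onset_days_median"):
        table[col] = table[col].fillna(0.0)
    return table


# ---------------------------------------------------------------------------
# train-only feature transforms


@dataclass(frozen=True)
class TransformSpec:
    """A frozen feature transform fitted on training data only."""

    method: str  # "standardize" | "quantile" | "none"
    columns: tuple[str, ...]
    params: dict

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return apply_transform(self, X)


def fit_transform(
    X: pd.DataFrame, method: str, columns: Optional[Iterable[str]] = None
) -> tuple[TransformSpec, pd.DataFrame]:
    """Fit a transform on `X` (training data) and return (spec, transformed).

    standardize: per-feature (x - mean) / sd; a constant feature maps to 0.
    quantile: monotone map of training ranks onto [0, 1], applied to held-out
    data by linear interpolation; a constant feature maps to 0.5.
    """
    cols = tuple(columns) if columns is not None else tuple(X.columns)
    if method == "none":
        spec = TransformSpec("none", cols, {})
        return spec, X[list(cols)].copy()
    if method == "standardize":
        sub = X[list(cols)].to_numpy(dtype=float)
        means = sub.mean(axis=0)
        sds = sub.std(axis=0, ddof=0)
        sds = np.where(sds == 0, 1.0, sds)
        spec = TransformSpec("standardize", cols, {"mean": means, "sd": sds})
        return spec, apply_transform(spec, X)
    if method == "quantile":
        grids = {}
        for col in cols:
            xs = np.sort(X[col].to_numpy(dtype=float))
            grids[col] = xs
        spec = TransformSpec("quantile", cols, {"grids": grids})
        return spec, apply_transform(spec, X)
    raise ValueError(f"unknown transform method {method!r}")


def apply_transform(spec: TransformSpec, X: pd.DataFrame) -> pd.DataFrame:
    sub = X[list(spec.columns)]
    if spec.method == "none":
        return sub.copy()
    if spec.method == "standardize":
        arr = (sub.to_numpy(dtype=float) - spec.params["mean"]) / spec.params["sd"]
        return pd.DataFrame(arr, columns=list(spec.columns), index=sub.index)
    if spec.method == "quantile":
        out = {}
        for col in spec.columns:
            xs = spec.params["grids"][col]
            v = sub[col].to_numpy(dtype=float)
            if len(xs) < 2 or xs[0] == xs[-1]:
                out[col] = np.full(len(v), 0.5)
            else:
                qs = np.linspace(0.0, 1.0, len(xs))
                out[col] = np.interp(v, xs, qs)
        return pd.DataFrame(out, index=sub.index)
    raise ValueError(f"unknown transform method {spec.method!r}")
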