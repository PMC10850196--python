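"""Loading, validating and cleaning spontaneous-report tables.

The database is modelled on the four-table layout of national
spontaneous-reporting systems: DEMO (one row per case: patient
characteristics and receipt quarter), DRUG (drug entries with role, start
date, OTC flag, action and rechallenge), REAC (reaction rows with preferred
term, onset date, outcome and follow-up version) and HIST (medical history).
The CSV schemas are the ones written by :mod:`pvlabel.simulate`:

    demo.csv: case_id, version, sex, age_band, weight_band, quarter_received
    drug.csv: case_id, drug_code, role, start_date, otc_flag, action, rechallenge
    reac.csv: case_id, version, pt_name, onset_date, outcome
    hist.csv: case_id, condition

Cleaning applies three exclusion rules before any tabulation, at the
case x reaction record level:

1. records whose reaction onset precedes the first dose of the case's
   suspected drugs;
2. duplicate records sharing (case_id, PT name, onset date), keeping one;
3. records whose suspected drug is an over-the-counter product.

All downstream tabulation considers suspected-role drug entries only.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .quarters import Quarter

DRUG_ROLES = ("suspected", "concomitant", "interacting")
OUTCOMES = ("recovered", "recovering", "unrecovered", "death", "unknown")
ACTIONS = ("continued", "discontinued", "unknown")
RECHALLENGE = ("readministered", "not_readministered", "unknown")

SCHEMAS = {
    "demo": ["case_id", "version", "sex", "age_band", "weight_band", "quarter_received"],
    "drug": ["case_id", "drug_code", "role", "start_date", "otc_flag", "action", "rechallenge"],
    "reac": ["case_id", "version", "pt_name", "onset_date", "outcome"],
    "hist": ["case_id", "condition"],
}


class LoadError(ValueError):
    """Malformed input table; the message names the file and row."""


@dataclass(frozen=True)
class DrugEntry:
    drug_code: str
    role: str = "suspected"
    start_date: Optional[dt.date] = None
    otc_flag: bool = False
    action: str = "unknown"
    rechallenge: str = "unknown"


@dataclass(frozen=True)
class ReactionEntry:
    pt_name: str
    onset_date: Optional[dt.date] = None
    outcome: str = "unknown"
    version: int = 1


@dataclass
class ReportCase:
    """One spontaneous report (latest follow-up view of a case)."""

    case_id: str
    quarter_received: Quarter
    version: int = 1
    sex: Optional[str] = None
    age_band: Optional[str] = None
    weight_band: Optional[str] = None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[ReactionEntry] = field(default_factory=list)
    history: list[str] = field(default_factory=list)

    def suspected(self) -> list[DrugEntry]:
        return [d for d in self.drugs if d.role == "suspected"]

    def earliest_suspected_start(self) -> Optional[dt.date]:
        starts = [d.start_date for d in self.suspected() if d.start_date is not None]
        return min(starts) if starts else None


@dataclass
class ExclusionLog:
    """Per-rule exclusion counts; records are case x reaction rows."""

    pre_admin_onset: int = 0
    duplicate: int = 0
    otc: int = 0
    retained: int = 0

    @property
    def total_input(self) -> int:
        return self.pre_admin_onset + self.duplicate + self.otc + self.retained

    def to_dict(self) -> dict:
        return {
            "pre_admin_onset": self.pre_admin_onset,
            "duplicate": self.duplicate,
            "otc": self.otc,
            "retained": self.retained,
        }


def _parse_date(value: str, file: str, row: int) -> Optional[dt.date]:
    value = str(value).strip()
    if not value:
        return None
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise LoadError(f"{file}, row {row}: unparseable date {value!r}") from exc


def _read_table(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise LoadError(f"missing input file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: schema mismatch, missing columns {missing}")
    return df


def load_reports(indir: "str | Path") -> list[ReportCase]:
    """Load the four report tables from `indir`, joined on case_id.

    Raises :class:`LoadError` naming the file and 1-based data row for any
    malformed value or referential-integrity violation (DRUG/REAC/HIST rows
    whose case_id is absent from DEMO).
    """
    indir = Path(indir)
    demo = _read_table(indir / "demo.csv", "demo")
    drug = _read_table(indir / "drug.csv", "drug")
    reac = _read_table(indir / "reac.csv", "reac")
    hist = _read_table(indir / "hist.csv", "hist")

    cases: dict[str, ReportCase] = {}
    for i, row in enumerate(demo.itertuples(index=False), start=1):
        cid = str(row.case_id).strip()
        if not cid:
            raise LoadError(f"demo.csv, row {i}: empty case_id")
        if cid in cases:
            raise LoadError(f"demo.csv, row {i}: duplicate case_id {cid!r}")
        try:
            quarter = Quarter.parse(row.quarter_received)
        except ValueError as exc:
            raise LoadError(f"demo.csv, row {i}: {exc}") from exc
        try:
            version = int(row.version) if str(row.version).strip() else 1
        except ValueError as exc:
            raise LoadError(f"demo.csv, row {i}: bad version {row.version!r}") from exc
        if version < 1:
            raise LoadError(f"demo.csv, row {i}: version must be >= 1, got {version}")
        cases[cid] = ReportCase(
            case_id=cid,
            quarter_received=quarter,
            version=version,
            sex=str(row.sex).strip() or None,
            age_band=str(row.age_band).strip() or None,
            weight_band=str(row.weight_band).strip() or None,
        )

    def _case(cid: str, file: str, i: int) -> ReportCase:
        cid = str(cid).strip()
        if cid not in cases:
            raise LoadError(f"{file}, row {i}: case_id {cid!r} absent from demo.csv")
        return cases[cid]

    for i, row in enumerate(drug.itertuples(index=False), start=1):
        role = str(row.role).strip()
        if role not in DRUG_ROLES:
            raise LoadError(f"drug.csv, row {i}: unknown role {role!r}")
        _case(row.case_id, "drug.csv", i).drugs.append(
            DrugEntry(
                drug_code=str(row.drug_code).strip(),
                role=role,
                start_date=_parse_date(row.start_date, "drug.csv", i),
                otc_flag=str(row.otc_flag).strip() in ("1", "true", "True"),
                action=str(row.action).strip() or "unknown",
                rechallenge=str(row.rechallenge).strip() or "unknown",
            )
        )

    for i, row in enumerate(reac.itertuples(index=False), start=1):
        pt = str(row.pt_name).strip()
        if not pt:
            raise LoadError(f"reac.csv, row {i}: empty pt_name")
        try:
            version = int(row.version) if str(row.version).strip() else 1
        except ValueError as exc:
            raise LoadError(f"reac.csv, row {i}: bad version {row.version!r}") from exc
        _case(row.case_id, "reac.csv", i).reactions.append(
            ReactionEntry(
                pt_name=pt,
                onset_date=_parse_date(row.onset_date, "reac.csv", i),
                outcome=str(row.outcome).strip() or "unknown",
                version=version,
            )
        )

    for i, row in enumerate(hist.itertuples(index=False), start=1):
        cond = str(row.condition).strip()
        if cond:
            _case(row.case_id, "hist.csv", i).history.append(cond)

    return list(cases.values())


def clean_reports(cases: Iterable[ReportCase]) -> tuple[list[ReportCase], ExclusionLog]:
    """Apply the three exclusion rules; returns cleaned cases and counts.

    Rules run in order (pre-administration onset, duplicates, OTC); each
    excluded record is counted once, under the first rule that removes it.
    Rule 1 requires both the onset date and the earliest suspected-drug start
    date to be present — a record with either date missing is retained, since
    exclusion needs positive evidence of precedence.  Duplicate sets keep the
    highest-version record (ties broken by outcome string, so the result does
    not depend on input order).  Rule 3 removes every record of a case whose
    suspected drugs include an OTC product.
    """
    log = ExclusionLog()
    cleaned: list[ReportCase] = []
    for case in sorted(cases, key=lambda c: c.case_id):
        earliest = case.earliest_suspected_start()
        survivors: list[ReactionEntry] = []
        for r in case.reactions:
            if (
                r.onset_date is not None
                and earliest is not None
                and r.onset_date < earliest
            ):
                log.pre_admin_onset += 1
            else:
                survivors.append(r)

        best: dict[tuple, ReactionEntry] = {}
        for r in survivors:
            key = (r.pt_name, r.onset_date)
            prior = best.get(key)
            if prior is None or (r.version, r.outcome) > (prior.version, prior.outcome):
                best[key] = r
        log.duplicate += len(survivors) - len(best)
        deduped = [r for r in survivors if best[(r.pt_name, r.onset_date)] is r]

        if any(d.otc_flag for d in case.suspected()):
            log.otc += len(deduped)
            continue
        if deduped:
            log.retained += len(deduped)
            cleaned.append(replace(case, reactions=deduped,
                                   drugs=list(case.drugs), history=list(case.history)))
    return cleaned, log


def write_cases(cases: Iterable[ReportCase], outdir: "str | Path") -> dict[str, Path]:
    """Write cases back to the four-table CSV layout (inverse of load)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    demo_rows, drug_rows, reac_rows, hist_rows = [], [], [], []
    for c in sorted(cases, key=lambda c: c.case_id):
        demo_rows.append(
            (c.case_id, c.version, c.sex or "", c.age_band or "", c.weight_band or "",
             str(c.quarter_received))
        )
        for d in c.drugs:
            drug_rows.append(
                (c.case_id, d.drug_code, d.role,
                 d.start_date.isoformat() if d.start_date else "",
                 int(d.otc_flag), d.action, d.rechallenge)
            )
        for r in c.reactions:
            reac_rows.append(
                (c.case_id, r.version, r.pt_name,
                 r.onset_date.isoformat() if r.onset_date else "", r.outcome)
            )
        for h in c.history:
            hist_rows.append((c.case_id, h))
    paths = {}
    for name, rows in (("demo", demo_rows), ("drug", drug_rows),
                       ("reac", reac_rows), ("hist", hist_rows)):
        path = outdir / f"{name}.csv"
        pd.DataFrame(rows, columns=SCHEMAS[name]).to_csv(path, index=False)
        paths[name] = path
    return paths
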