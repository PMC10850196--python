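"""Synthetic spontaneous-report databases with known ground truth.

Real spontaneous-reporting data cannot ship with the package, so every
downstream stage is exercised against a generator whose truth is known.  The
generator emulates, per drug-disease pair, a quarterly Poisson report stream:
baseline noise pairs arrive at ``baseline_rate`` reports per quarter, while
*planted* pairs are elevated to ``baseline_rate * rate_multiplier`` during a
ramp of ``ramp_quarters`` quarters immediately preceding a logged label
revision — the accumulation of domestic cases that triggers a revision.

Each report is one case: one patient, one suspected drug, one reaction whose
preferred term is drawn from the packaged grouping for the pair's disease.
Realistic blemishes are injected at configured probabilities: missing onset /
start dates and demographics, death outcomes, rechallenge and discontinuation
flags, duplicate reaction rows, follow-up versions sharing a case id,
over-the-counter drugs, and onset dates preceding the first dose.

Output is deterministic for a fixed (config, seed): tables are built in a
fixed iteration order from a single ``numpy`` generator.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .grouping import GroupingMap, load_grouping
from .quarters import Quarter
from .report_store import SCHEMAS

SEXES = ("male", "female")
AGE_BANDS = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")
WEIGHT_BANDS = ("40-49kg", "50-59kg", "60-69kg", "70-79kg", "80kg+")
NONFATAL_OUTCOMES = ("recovered", "recovering", "unrecovered", "unknown")
HISTORY_TERMS = ("hypertension", "diabetes mellitus", "dyslipidaemia",
                 "chronic kidney disease", "asthma")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class PlantedPair:
    """A drug-disease pair with an elevated report stream and a logged revision."""

    drug: str
    disease: str
    rate_multiplier: float
    ramp_quarters: int
    revision_quarter: str  # "YYYYQn"


@dataclass(frozen=True)
class RevisionRecord:
    drug_code: str
    disease: str
    announce_quarter: str
    reason: str  # domestic | domestic_and_overseas | overseas | other


@dataclass
class GroundTruth:
    positive_pairs: set[tuple[str, str]]
    revision_log: list[RevisionRecord]


@dataclass
class SimConfig:
    n_drugs: int = 20
    n_diseases: int = 10
    n_quarters: int = 16
    start_quarter: str = "2014Q1"
    baseline_rate: float = 0.25
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    missing_date_prob: float = 0.15
    death_prob: float = 0.05
    rechallenge_prob: float = 0.02
    discontinuation_prob: float = 0.25
    otc_drug_fraction: float = 0.02
    duplicate_prob: float = 0.03
    pre_admin_onset_prob: float = 0.01
    onset_day_distribution: dict = field(
        default_factory=lambda: {"name": "exponential", "scale": 20.0}
    )
    followup_versions_mean: float = 0.3
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self, gmap: Optional[GroupingMap] = None) -> None:
        if gmap is None:
            gmap = load_grouping()
        if self.n_drugs < 1:
            raise ConfigError("n_drugs must be >= 1")
        if not 1 <= self.n_diseases <= len(gmap):
            raise ConfigError(
                f"n_diseases must be in 1..{len(gmap)} (packaged grouping size)"
            )
        if self.n_quarters < 1:
            raise ConfigError("n_quarters must be >= 1")
        if self.baseline_rate < 0:
            raise ConfigError("baseline_rate must be nonnegative")
        for name in ("missing_date_prob", "death_prob", "rechallenge_prob",
                     "discontinuation_prob", "otc_drug_fraction", "duplicate_prob",
                     "pre_admin_onset_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
        if self.followup_versions_mean < 0:
            raise ConfigError("followup_versions_mean must be nonnegative")
        start = Quarter.parse(self.start_quarter)
        end = start + (self.n_quarters - 1)
        drugs = set(self.drug_codes())
        diseases = set(self.disease_names(gmap))
        seen = set()
        for p in self.planted_pairs:
            if p.drug not in drugs:
                raise ConfigError(f"planted_pairs: unknown drug {p.drug!r}")
            if p.disease not in diseases:
                raise ConfigError(f"planted_pairs: unknown disease {p.disease!r}")
            # >= 1 (not > 1) so that label-only null benchmarks can plant
            # revisions without any rate elevation
            if p.rate_multiplier < 1:
                raise ConfigError("planted_pairs: rate_multiplier must be >= 1")
            if p.ramp_quarters < 1:
                raise ConfigError("planted_pairs: ramp_quarters must be >= 1")
            rev = Quarter.parse(p.revision_quarter)
            if not start <= rev <= end:
                raise ConfigError(
                    f"planted_pairs: revision_quarter {rev} outside the simulated period"
                )
            if rev - start < p.ramp_quarters + 2:
                raise ConfigError(
                    "planted_pairs: revision_quarter must be >= ramp_quarters + 2 "
                    "quarters after the simulation start"
                )
            if (p.drug, p.disease) in seen:
                raise ConfigError(f"planted_pairs: duplicate pair {(p.drug, p.disease)}")
            seen.add((p.drug, p.disease))
        dist = self.onset_day_distribution
        if dist.get("name") not in ("exponential", "lognormal", "constant", "uniform"):
            raise ConfigError(
                f"onset_day_distribution: unknown distribution {dist.get('name')!r}"
            )

    def drug_codes(self) -> list[str]:
        return [f"D{i:03d}" for i in range(self.n_drugs)]

    def disease_names(self, gmap: Optional[GroupingMap] = None) -> list[str]:
        if gmap is None:
            gmap = load_grouping()
        return gmap.diseases()[: self.n_diseases]

    @property
    def quarters(self) -> list[Quarter]:
        start = Quarter.parse(self.start_quarter)
        return [start + i for i in range(self.n_quarters)]


@dataclass
class SimulatedDatabase:
    tables: dict[str, pd.DataFrame]   # demo / drug / reac / hist
    revisions: list[RevisionRecord]
    truth: GroundTruth
    config: SimConfig


def _sample_onset_days(rng: np.random.Generator, dist: dict) -> int:
    name = dist["name"]
    if name == "exponential":
        return int(rng.exponential(dist.get("scale", 20.0)))
    if name == "lognormal":
        return int(rng.lognormal(dist.get("mean", 2.5), dist.get("sigma", 1.0)))
    if name == "constant":
        return int(dist.get("value", 14))
    if name == "uniform":
        return int(rng.integers(int(dist.get("low", 0)), int(dist.get("high", 90)) + 1))
    raise ConfigError(f"unknown onset distribution {name!r}")


def generate_database(config: SimConfig, gmap: Optional[GroupingMap] = None) -> SimulatedDatabase:
    """Generate the four report tables plus the revision log and ground truth."""
    if gmap is None:
        gmap = load_grouping()
    config.validate(gmap)
    rng = np.random.default_rng(config.seed)

    drugs = config.drug_codes()
    diseases = config.disease_names(gmap)
    quarters = config.quarters
    planted = {(p.drug, p.disease): p for p in config.planted_pairs}
    planted_drugs = {p.drug for p in config.planted_pairs}

    n_otc = int(round(config.otc_drug_fraction * config.n_drugs))
    non_planted = [d for d in drugs if d not in planted_drugs]
    otc_drugs = set(rng.choice(non_planted, size=min(n_otc, len(non_planted)),
                               replace=False)) if n_otc else set()

    demo_rows, drug_rows, reac_rows, hist_rows = [], [], [], []
    case_counter = 0

    for drug in drugs:
        for disease in diseases:
            plant = planted.get((drug, disease))
            ramp: set[int] = set()
            if plant is not None:
                rev = Quarter.parse(plant.revision_quarter)
                ramp = {(rev - k).index for k in range(1, plant.ramp_quarters + 1)}
            for quarter in quarters:
                rate = config.baseline_rate
                if plant is not None and quarter.index in ramp:
                    rate *= plant.rate_multiplier
                n_reports = rng.poisson(rate)
                for _ in range(n_reports):
                    case_counter += 1
                    cid = f"C{case_counter:07d}"
                    _emit_case(
                        rng, config, gmap, cid, drug, disease, quarter,
                        drug in otc_drugs, demo_rows, drug_rows, reac_rows, hist_rows,
                    )

    tables = {
        "demo": pd.DataFrame(demo_rows, columns=SCHEMAS["demo"]),
        "drug": pd.DataFrame(drug_rows, columns=SCHEMAS["drug"]),
        "reac": pd.DataFrame(reac_rows, columns=SCHEMAS["reac"]),
        "hist": pd.DataFrame(hist_rows, columns=SCHEMAS["hist"]),
    }
    revisions = [
        RevisionRecord(p.drug, p.disease, str(Quarter.parse(p.revision_quarter)), "domestic")
        for p in config.planted_pairs
    ]
    truth = GroundTruth(
        positive_pairs={(p.drug, p.disease) for p in config.planted_pairs},
        revision_log=list(revisions),
    )
    return SimulatedDatabase(tables, revisions, truth, config)


def _emit_case(rng, config, gmap, cid, drug, disease, quarter, otc,
               demo_rows, drug_rows, reac_rows, hist_rows):
    q_start = quarter.start_date()
    onset = q_start + dt.timedelta(days=int(rng.integers(0, quarter.n_days())))
    if rng.random() < config.pre_admin_onset_prob:
        # anomaly: onset precedes the first dose by 1-30 days
        start = onset
        onset = start - dt.timedelta(days=int(rng.integers(1, 31)))
    else:
        start = onset - dt.timedelta(days=_sample_onset_days(rng, config.onset_day_distribution))

    sex = rng.choice(SEXES)
    age = rng.choice(AGE_BANDS)
    weight = rng.choice(WEIGHT_BANDS)
    if rng.random() < config.missing_date_prob:
        sex = ""
    if rng.random() < config.missing_date_prob:
        age = ""
    if rng.random() < config.missing_date_prob:
        weight = ""
    onset_s = "" if rng.random() < config.missing_date_prob else onset.isoformat()
    start_s = "" if rng.random() < config.missing_date_prob else start.isoformat()

    outcome = "death" if rng.random() < config.death_prob else str(rng.choice(NONFATAL_OUTCOMES))
    action = "discontinued" if rng.random() < config.discontinuation_prob else str(
        rng.choice(("continued", "unknown")))
    rechallenge = "readministered" if rng.random() < config.rechallenge_prob else str(
        rng.choice(("not_readministered", "unknown")))
    pts = sorted(gmap.pts_for(disease))
    pt = str(rng.choice(pts))
    n_versions = 1 + int(rng.poisson(config.followup_versions_mean))

    demo_rows.append((cid, n_versions, sex, age, weight, str(quarter)))
    drug_rows.append((cid, drug, "suspected", start_s, int(otc), action, rechallenge))
    for v in range(1, n_versions + 1):
        reac_rows.append((cid, v, pt, onset_s, outcome))
    if rng.random() < config.duplicate_prob:
        # duplicate record sharing (case_id, PT, onset date)
        reac_rows.append((cid, n_versions, pt, onset_s, outcome))
    if rng.random() < 0.3:
        hist_rows.append((cid, str(rng.choice(HISTORY_TERMS))))


def write_database(db: SimulatedDatabase, outdir: "str | Path") -> dict[str, Path]:
    """Write demo/drug/reac/hist plus revisions.csv, listed.csv and truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in db.tables.items():
        paths[name] = outdir / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    rev = pd.DataFrame(
        [(r.drug_code, r.disease, r.announce_quarter, r.reason) for r in db.revisions],
        columns=["drug", "disease", "quarter", "reason"],
    )
    paths["revisions"] = outdir / "revisions.csv"
    rev.to_csv(paths["revisions"], index=False)
    # pairs listed in the label at period end = all revised pairs
    listed = rev[["drug", "disease"]]
    paths["listed"] = outdir / "listed.csv"
    listed.to_csv(paths["listed"], index=False)
    truth = pd.DataFrame(sorted(db.truth.positive_pairs), columns=["drug", "disease"])
    paths["truth"] = outdir / "truth.csv"
    truth.to_csv(paths["truth"], index=False)
    return paths


# ---------------------------------------------------------------------------
# null 2x2 tables for interval-calibration studies


def simulate_null_tables(
    n_replicates: int,
    n_cases: int,
    p_drug: float,
    p_adr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Proportional-reporting null: no drug-reaction association.

    Each replicate classifies `n_cases` independent cases with independent
    drug-membership probability `p_drug` and target-reaction probability
    `p_adr`, so the true odds ratio is exactly 1.  Returns an
    (n_replicates, 4) array of (a, b, c, d) counts.
    """
    probs = [
        p_drug * p_adr,
        (1 - p_drug) * p_adr,
        p_drug * (1 - p_adr),
        (1 - p_drug) * (1 - p_adr),
    ]
    return rng.multinomial(n_cases, probs, size=n_replicates)


# ---------------------------------------------------------------------------
# the benchmark study conditions


def study_config(seed: int = 0, planted: bool = True, n_positives: int = 30) -> SimConfig:
    """The default benchmark database: 60 drugs x 40 diseases over 24 quarters.

    Plants `n_positives` elevated pairs (rate multiplier 10 over an
    eight-quarter ramp) with revisions staggered through the second half of
    the period.  With ``planted=False`` the same revisions are logged but the
    rate multiplier is 1 — a label-only null with no signal in the data.
    """
    gmap = load_grouping()
    n_drugs, n_diseases = 60, 40
    diseases = gmap.diseases()[:n_diseases]
    pairs = []
    for i in range(n_positives):
        drug = f"D{i:03d}"
        disease = diseases[(i * 7) % n_diseases]
        rev = Quarter.parse("2017Q1") + (i % 12)  # 2017Q1 .. 2019Q4
        pairs.append(
            PlantedPair(
                drug=drug,
                disease=disease,
                rate_multiplier=10.0 if planted else 1.0,
                ramp_quarters=8,
                revision_quarter=str(rev),
            )
        )
    return SimConfig(
        n_drugs=n_drugs,
        n_diseases=n_diseases,
        n_quarters=24,
        start_quarter="2014Q1",
        baseline_rate=0.25,
        planted_pairs=pairs,
        seed=seed,
    )
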