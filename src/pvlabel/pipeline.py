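"""Stage orchestration: simulate -> clean -> cohort -> features -> signals -> train.

Every stage is a plain function over files so runs are re-loadable and
individually re-runnable; ``run_all`` chains them under one YAML-style
config dict and writes a manifest recording seeds, row counts and output
checksums.  ``run_experiment`` is the in-memory equivalent used by the
benchmark scripts and tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .bench import ModelSpec, train_and_evaluate
from .cohort import build_cohort, load_listed, load_revisions
from .disproportionality import crosstab_vs_revisions, signal_table, SignalDecision
from .features import (
    CaseIndex,
    FEATURE_NAMES,
    compute_feature_table,
    finalize_features,
    impute_onset_days,
)
from .grouping import load_grouping
from .quarters import Quarter
from .report_store import clean_reports, load_reports, write_cases
from .simulate import PlantedPair, SimConfig, generate_database, write_database

logger = logging.getLogger(__name__)

STAGES = ("simulate", "clean", "cohort", "features", "signals", "crosstab", "train")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def sim_config_from_dict(cfg: dict, seed: int) -> SimConfig:
    cfg = dict(cfg)
    planted = [PlantedPair(**p) for p in cfg.pop("planted_pairs", [])]
    return SimConfig(planted_pairs=planted, seed=seed, **cfg)


# -- individual stages -------------------------------------------------------


def stage_simulate(sim_cfg: SimConfig, outdir: Path) -> dict:
    db = generate_database(sim_cfg)
    paths = write_database(db, outdir)
    return {"rows": {k: len(db.tables[k]) for k in db.tables},
            "outputs": {k: str(v) for k, v in paths.items()}}


def stage_clean(indir: Path, outdir: Path, log_path: Optional[Path] = None) -> dict:
    cases = load_reports(indir)
    cleaned, exclusions = clean_reports(cases)
    write_cases(cleaned, outdir)
    if log_path is not None:
        log_path.parent.mkdir(parents=True, exist_ok=True)
        log_path.write_text(json.dumps(exclusions.to_dict(), indent=2))
    return {"cases_in": len(cases), "cases_out": len(cleaned),
            "exclusions": exclusions.to_dict()}


def stage_cohort(
    indir: Path,
    revisions_path: Path,
    listed_path: Path,
    period: tuple[str, str],
    out_path: Path,
    lag_quarters: int = 2,
    negative_as_of: str = "period_end",
) -> dict:
    if not Path(revisions_path).exists():
        raise StageError(f"cohort: revisions file not found: {revisions_path}")
    if not Path(listed_path).exists():
        raise StageError(f"cohort: listed-pairs file not found: {listed_path}")
    cases, _ = clean_reports(load_reports(indir))
    gmap = load_grouping()
    result = build_cohort(
        cases, load_revisions(revisions_path), load_listed(listed_path), gmap,
        period, lag_quarters=lag_quarters, negative_as_of=negative_as_of,
    )
    out_path.parent.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out_path, index=False)
    return {"positives": len(result.positives), "negatives": len(result.negatives),
            "excluded_revisions": len(result.excluded_revisions)}


def stage_features(indir: Path, cohort_path: Path, out_path: Path) -> dict:
    from .cohort import LabeledPair

    cases, _ = clean_reports(load_reports(indir))
    gmap = load_grouping()
    cohort_df = pd.read_csv(cohort_path, dtype=str, keep_default_na=False)
    pairs = [
        LabeledPair(r.drug, r.disease, r.label, Quarter.parse(r.as_of))
        for r in cohort_df.itertuples(index=False)
    ]
    index = CaseIndex(cases, gmap)
    table = compute_feature_table(pairs, index)
    table = finalize_features(impute_onset_days(table, index))
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, index=False)
    return {"pairs": len(table), "features": len(FEATURE_NAMES)}


def stage_signals(indir: Path, as_of: str, out_path: Path,
                  n_min: int = 3, chi_min: float = 4.0, prr_min: float = 2.0) -> dict:
    cases, _ = clean_reports(load_reports(indir))
    gmap = load_grouping()
    table = signal_table(cases, gmap, as_of, n_min=n_min, chi_min=chi_min, prr_min=prr_min)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, index=False)
    return {"pairs": len(table), "detected": int(table["detected"].sum())}


def stage_crosstab(signals_path: Path, revisions_path: Path, out_path: Path) -> dict:
    signals = pd.read_csv(signals_path)
    revisions = load_revisions(revisions_path)
    revised = {(r.drug_code, r.disease) for r in revisions}
    decisions = [
        SignalDecision(r.drug, r.disease, int(r.a), float(r.chisq), float(r.prr),
                       bool(r.detected))
        for r in signals.itertuples(index=False)
    ]
    summary = crosstab_vs_revisions(decisions, revised)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(summary, indent=2))
    return summary


def stage_train(
    features_path: Path,
    out_path: Path,
    spec: ModelSpec = ModelSpec(),
    efs_sizes=(1, 2),
    ratio: float = 0.7,
    k: int = 5,
    tune_iterations: int = 0,
    seed: int = 0,
) -> dict:
    table = pd.read_csv(features_path)
    report = train_and_evaluate(
        table, spec=spec, efs_sizes=efs_sizes, ratio=ratio, k=k,
        tune_iterations=tune_iterations, seed=seed,
    )
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(report.to_dict(), indent=2))
    return report.to_dict()


# -- the whole pipeline ------------------------------------------------------


def run_all(config: dict) -> dict:
    """Run every stage from one config dict; returns (and writes) the manifest.

    Config keys: ``seed``, ``outdir``, ``simulate`` (SimConfig fields),
    ``period`` {start, end}, ``cohort`` {lag_quarters}, ``train``
    {efs_sizes, ratio, cv, tune_iterations, model, transform, C, gamma},
    ``signals`` {n_min, chi_min, prr_min}.
    """
    seed = int(config.get("seed", 0))
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}}

    sim_cfg = sim_config_from_dict(config.get("simulate", {}), seed)
    period_cfg = config.get("period")
    if period_cfg:
        period = (str(period_cfg["start"]), str(period_cfg["end"]))
    else:
        quarters = sim_cfg.quarters
        period = (str(quarters[0]), str(quarters[-1]))

    raw = outdir / "raw"
    cleaned = outdir / "cleaned"

    def _run(name, fn, *args, **kwargs):
        try:
            info = fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"status": "completed", **_jsonable(info)}
        logger.info("stage %s completed: %s", name, info)

    _run("simulate", stage_simulate, sim_cfg, raw)
    _run("clean", stage_clean, raw, cleaned, outdir / "exclusions.json")
    _run("cohort", stage_cohort, cleaned, raw / "revisions.csv", raw / "listed.csv",
         period, outdir / "cohort.csv", int(config.get("cohort", {}).get("lag_quarters", 2)))
    _run("features", stage_features, cleaned, outdir / "cohort.csv", outdir / "features.csv")
    sig = config.get("signals", {})
    _run("signals", stage_signals, cleaned, period[1], outdir / "signals.csv",
         int(sig.get("n_min", 3)), float(sig.get("chi_min", 4.0)), float(sig.get("prr_min", 2.0)))
    _run("crosstab", stage_crosstab, outdir / "signals.csv", raw / "revisions.csv",
         outdir / "crosstab.json")
    tr = config.get("train", {})
    spec = ModelSpec(
        kind=tr.get("model", "rbf_svm"),
        C=float(tr.get("C", 10.0)),
        gamma=float(tr.get("gamma", 0.5)),
        transform=tr.get("transform", "standardize"),
        seed=seed,
    )
    _run("train", stage_train, outdir / "features.csv", outdir / "report.json",
         spec, tuple(tr.get("efs_sizes", (1, 2))), float(tr.get("ratio", 0.7)),
         int(tr.get("cv", 3)), int(tr.get("tune_iterations", 0)), seed)

    checksums = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            checksums[str(path.relative_to(outdir))] = _sha256(path)
    manifest["checksums"] = checksums
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


# -- in-memory end-to-end benchmark ------------------------------------------


def run_experiment(
    sim_cfg: SimConfig,
    efs_sizes=(1, 2),
    ratio: float = 0.7,
    k: int = 3,
    tune_iterations: int = 20,
    spec: ModelSpec = ModelSpec(),
    seed: Optional[int] = None,
) -> dict:
    """Generate a database, build the cohort and features, train, evaluate.

    Returns the model report plus cohort counts, the exclusion log, the
    conventional signal-rule crosstab against the planted revisions, and the
    ground truth recovery check.  Deterministic given the config's seed.
    """
    seed = sim_cfg.seed if seed is None else seed
    gmap = load_grouping()
    db = generate_database(sim_cfg, gmap)
    cases = _cases_from_tables(db)
    cleaned, exclusions = clean_reports(cases)
    quarters = sim_cfg.quarters
    period = (quarters[0], quarters[-1])
    listed = {(r.drug_code, r.disease) for r in db.revisions}
    cohort = build_cohort(
        cleaned, db.revisions, listed, gmap, period, negative_as_of="matched"
    )
    index = CaseIndex(cleaned, gmap)
    table = compute_feature_table(cohort.pairs, index)
    table = finalize_features(impute_onset_days(table, index))

    report = train_and_evaluate(
        table, spec=spec, efs_sizes=efs_sizes, ratio=ratio, k=k,
        tune_iterations=tune_iterations, seed=seed,
    )

    sig = signal_table(cleaned, gmap, period[1])
    decisions = [
        SignalDecision(r.drug, r.disease, int(r.a), float(r.chisq), float(r.prr),
                       bool(r.detected))
        for r in sig.itertuples(index=False)
    ]
    crosstab = crosstab_vs_revisions(decisions, listed)

    recovered = {(p.drug, p.disease) for p in cohort.positives}
    return {
        "report": report,
        "feature_table": table,
        "cohort": {
            "positives": len(cohort.positives),
            "negatives": len(cohort.negatives),
            "recovered_truth": recovered == db.truth.positive_pairs,
        },
        "exclusions": exclusions.to_dict(),
        "signal_crosstab": crosstab,
        "truth": db.truth,
    }


def _cases_from_tables(db) -> list:
    """Materialise ReportCase objects from in-memory simulated tables."""
    import tempfile

    from .report_store import load_reports as _load

    with tempfile.TemporaryDirectory() as tmp:
        write_database(db, tmp)
        return _load(tmp)
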