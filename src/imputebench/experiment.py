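"""End-to-end experiment driver: cohort -> amputation -> imputation ->
decision-impact metrics -> paired comparisons -> report files.

The canonical experiment generates one synthetic cohort, computes the
complete-data reference metrics, then for each of the 18 missing scenarios
(3 mechanisms x 6 proportions) runs the eight imputation methods and
scores each completed dataset with the downstream discharge model.  The
run is fully deterministic given the master seed; per-cell failures are
recorded and do not abort the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import amputation, cohort as cohortmod, imputers
from .amputation import CANONICAL_PROPORTIONS, MECHANISMS, enumerate_scenarios
from .cohort import generate_cohort, table2_profile
from .evaluation import (MetricSet, average_metrics, compute_metrics,
                         evaluate_scenario, fit_outcome_model,
                         youden_threshold)
from .imputers import METHODS, ImputerConfig, impute
from .stattests import compare_el

__all__ = ["ExperimentConfig", "ReportBundle", "run_experiment", "write_report"]

logger = logging.getLogger("imputebench")


@dataclasses.dataclass
class ExperimentConfig:
    """Everything needed to reproduce one benchmarking experiment."""

    cohort_mode: str = "exact"
    dependence: dict[tuple[str, str], float] | None = None
    seed: int = 0
    proportions: tuple[float, ...] = CANONICAL_PROPORTIONS
    mechanisms: tuple[str, ...] = MECHANISMS
    methods: tuple[str, ...] = METHODS
    profile: str = "full"          # "full" grids or the reduced "fast" ones
    threshold: float = 0.5
    threshold_mode: str = "fixed"  # or "youden"
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.cohort_mode not in ("exact", "stochastic"):
            raise ValueError(f"unknown cohort mode {self.cohort_mode!r}")
        if self.profile not in ("full", "fast"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.threshold_mode not in ("fixed", "youden"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        unknown = set(self.mechanisms) - set(MECHANISMS)
        if unknown:
            raise ValueError(f"unknown mechanisms {sorted(unknown)}")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def imputer_config(self) -> ImputerConfig:
        if self.profile == "fast":
            return ImputerConfig.fast(seed=self.seed)
        return ImputerConfig(seed=self.seed)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dependence"] = [
            [u, v, float(lam)] for (u, v), lam in (self.dependence or {}).items()
        ]
        d["proportions"] = list(self.proportions)
        d["mechanisms"] = list(self.mechanisms)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        dep = d.get("dependence") or []
        d["dependence"] = {(u, v): float(lam) for u, v, lam in dep} or None
        for key in ("proportions", "mechanisms", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class ReportBundle:
    """All tables produced by one experiment run."""

    results: pd.DataFrame    # long grid: mechanism, proportion, method, metrics
    averages: pd.DataFrame   # per mechanism x method, mean over proportions
    stats: pd.DataFrame      # paired-comparison table (may be empty)
    reference: MetricSet
    manifest: dict


def _reference_metrics(records: pd.DataFrame, config: ExperimentConfig) -> MetricSet:
    model = fit_outcome_model(records)
    labels = records[cohortmod.OUTCOME].to_numpy(dtype=int)
    threshold = config.threshold
    if config.threshold_mode == "youden":
        threshold = youden_threshold(model.probabilities, labels)
    return compute_metrics(model.probabilities, labels, threshold)


def run_experiment(config: ExperimentConfig) -> ReportBundle:
    """Run the full benchmarking experiment described by ``config``."""
    t_start = time.perf_counter()
    imp_config = config.imputer_config()
    profile = table2_profile()

    cohort = generate_cohort(profile, mode=config.cohort_mode,
                             dependence=config.dependence, seed=config.seed)
    reference = _reference_metrics(cohort.records, config)
    logger.info("cohort generated (n=%d); reference sens=%.3f auc=%.3f "
                "kappa=%.3f", cohort.n, reference.sensitivity,
                reference.auc, reference.kappa)

    rows: list[dict] = []
    cells: list[dict] = []
    for rep in range(config.replicates):
        scenarios = enumerate_scenarios(config.proportions, config.mechanisms,
                                        seed_base=config.seed + rep)
        for scenario in scenarios:
            incomplete = amputation.ampute(cohort, scenario)
            for method in config.methods:
                t0 = time.perf_counter()
                row = {
                    "replicate": rep,
                    "mechanism": scenario.mechanism,
                    "proportion": scenario.proportion,
                    "method": method,
                }
                try:
                    completed = impute(incomplete, method, imp_config)
                    result = evaluate_scenario(
                        completed, reference,
                        threshold=config.threshold,
                        threshold_mode=config.threshold_mode,
                    )
                    row.update(
                        sensitivity=result.metrics.sensitivity,
                        auc=result.metrics.auc,
                        kappa=result.metrics.kappa,
                        status="ok",
                    )
                    cells.append({
                        "replicate": rep,
                        "scenario": scenario.label,
                        "method": method,
                        "params": _jsonable(
                            completed.provenance.get("params")
                            or completed.provenance.get("stage1_params")
                        ),
                        "seconds": round(time.perf_counter() - t0, 3),
                    })
                except Exception as exc:  # per-cell failure, run continues
                    logger.warning("cell %s/%s failed: %s",
                                   scenario.label, method, exc)
                    row.update(sensitivity=np.nan, auc=np.nan, kappa=np.nan,
                               status=f"failed: {exc}")
                rows.append(row)
            logger.info("scenario %s done (%.1fs elapsed)",
                        scenario.label, time.perf_counter() - t_start)

    results = pd.DataFrame(rows)
    if config.replicates > 1:
        ok = results[results["status"] == "ok"]
        results = (
            ok.groupby(["mechanism", "proportion", "method"], sort=False)
            [["sensitivity", "auc", "kappa"]].mean().reset_index()
        )
        results["status"] = "ok"
    else:
        results = results.drop(columns=["replicate"])

    ok = results[results["status"] == "ok"]
    averages = (
        ok.groupby(["mechanism", "method"], sort=False)
        [["sensitivity", "auc", "kappa"]].mean().reset_index()
    )

    stats = pd.DataFrame()
    if "EL" in config.methods and len(config.methods) > 1 \
            and not (results["status"] != "ok").any():
        try:
            stats = compare_el(results)
        except ValueError as exc:
            logger.warning("paired comparison skipped: %s", exc)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "reference": {
            "sensitivity": reference.sensitivity,
            "auc": reference.auc,
            "kappa": reference.kappa,
        },
        "n_records": cohort.n,
        "cells": cells,
        "versions": _versions(),
        "elapsed_seconds": round(time.perf_counter() - t_start, 1),
    }
    return ReportBundle(results=results, averages=averages, stats=stats,
                        reference=reference, manifest=manifest)


def _jsonable(obj):
    if obj is None:
        return None
    return json.loads(json.dumps(obj, default=str))


def _versions() -> dict:
    import sklearn
    import scipy
    import statsmodels
    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def write_report(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write results.csv, averages.csv, stats.csv, manifest.json and one
    wide per-mechanism table (metric x proportion rows incl. an Average
    row, method columns)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, df in (("results.csv", bundle.results),
                     ("averages.csv", bundle.averages),
                     ("stats.csv", bundle.stats)):
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    for mechanism in bundle.results["mechanism"].unique():
        block = bundle.results[bundle.results["mechanism"] == mechanism]
        frames = []
        for metric in ("sensitivity", "auc", "kappa"):
            wide = block.pivot_table(index="proportion", columns="method",
                                     values=metric, sort=True)
            wide = wide[[m for m in bundle.results["method"].unique()
                         if m in wide.columns]]
            wide.loc["Average"] = wide.mean()
            wide = wide.round(3)
            wide.insert(0, "metric", metric)
            frames.append(wide.reset_index(names="proportion"))
        path = outdir / f"wide_{mechanism}.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        written.append(path)

    path = outdir / "manifest.json"
    path.write_text(json.dumps(bundle.manifest, indent=2, default=str))
    written.append(path)
    return written
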