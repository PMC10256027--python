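"""End-to-end orchestration: simulate/load -> preprocess -> fit -> validate.

One :func:`run` produces, per variety x analyte, a grouped leave-one-out
cross-validation with the configured latent-variable count and writes:

* ``report.csv``     — the headline table (value range, RMSEP, R^2,
                       RMSEP as % of range, sample/spectra counts)
* ``cv/*.csv``       — per-spectrum held-out predictions per cell
* ``models/*.json``  — the full-data PLS model per cell
* ``comparison.csv`` — per-analyte agreement of the two reference methods
* ``run.log``        — one line per CV fold, so any report number is traceable

Everything is stamped with the config hash and seed; a rerun with the
same config and seed reproduces the artifacts byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .chemometrics import (
    ChemometricsError,
    compare_methods,
    fit_pls,
    loo_cv,
    predict,
    rmsep_percent_of_range,
    save_model,
)
from .spectra import SpectraCollection, SpectraError, flag_outliers, preprocess
from .synthetic import SimulatedDataset, SimulationConfig, generate_dataset

__all__ = ["RunConfig", "run", "method_comparison_report", "read_report"]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "variety", "analyte", "value_min", "value_max", "rmsep_g_l",
    "r2_percent", "rmsep_percent_of_range", "n_samples", "n_spectra",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: an embedded :class:`SimulationConfig`, or
    paths to spectra + reference files written in the package formats.
    """

    output_dir: str | Path
    simulation: SimulationConfig | None = None
    spectra_path: str | Path | None = None
    reference_path: str | Path | None = None
    secondary_reference_path: str | Path | None = None
    analytes: tuple[str, ...] = mio.ANALYTES
    n_components: int = 6
    sg_window: int = 7
    sg_polyorder: int = 2
    outlier_k: float = 3.5
    seed: int | None = None           # overrides simulation.seed when given
    temperature_feature: bool = False  # harvester mode: T as extra predictor
    pooled: bool = False               # also fit one all-variety model set

    def __post_init__(self) -> None:
        sim = self.simulation is not None
        files = self.spectra_path is not None or self.reference_path is not None
        if sim == files:
            raise SpectraError(
                "exactly one input source required: embedded simulation "
                "config XOR spectra/reference file paths"
            )
        if files and (self.spectra_path is None or self.reference_path is None):
            raise SpectraError("file input needs both spectra_path and reference_path")


def _config_hash(config: RunConfig) -> str:
    doc = {
        "analytes": list(config.analytes),
        "n_components": config.n_components,
        "sg_window": config.sg_window,
        "sg_polyorder": config.sg_polyorder,
        "outlier_k": config.outlier_k,
        "seed": config.seed,
        "temperature_feature": config.temperature_feature,
        "pooled": config.pooled,
        "simulation": config.simulation.to_dict() if config.simulation else None,
        "spectra_path": str(config.spectra_path) if config.spectra_path else None,
        "reference_path": str(config.reference_path) if config.reference_path else None,
    }
    blob = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None:
            sim = replace(sim, seed=config.seed)
        ds = generate_dataset(sim)
        return ds.spectra, ds.primary_reference, ds.secondary_reference
    spectra = mio.read_spectra(config.spectra_path)
    primary = mio.read_reference(config.reference_path)
    secondary = None
    if config.secondary_reference_path is not None:
        secondary = mio.read_reference(config.secondary_reference_path)
    return spectra, primary, secondary


def _preprocess_variety(spectra, config: RunConfig):
    """Outlier screening then SNV + SG derivative for one variety."""
    coll = SpectraCollection(list(spectra))
    report = flag_outliers(coll, k=config.outlier_k)
    kept = [s for s, keep in zip(coll, report.kept) if keep]
    if report.n_excluded:
        logger.warning(
            "%s: excluded %d/%d spectra as referencing outliers",
            kept[0].variety if kept else "?", report.n_excluded, len(coll),
        )
    processed = [
        preprocess(s, window=config.sg_window, polyorder=config.sg_polyorder)
        for s in kept
    ]
    return processed, report


def _design_matrix(processed, config: RunConfig):
    X = np.vstack([s.values for s in processed])
    if config.temperature_feature:
        X = np.column_stack([X, [s.temperature_c for s in processed]])
    groups = np.array([s.sample_id for s in processed])
    temps = np.array([s.temperature_c for s in processed])
    return X, groups, temps


def _validate_cell(X, groups, temps, y_by_sample, variety, analyte, config, run_dir,
                   fh_log):
    y = np.array([y_by_sample[g] for g in groups])
    cv = loo_cv(X, y, groups, n_components=config.n_components, analyte=analyte)
    for fold_id, sid in enumerate(np.unique(groups)):
        held = groups == sid
        for pred, true in zip(cv.predictions[held], cv.truths[held]):
            fh_log.info(
                "fold variety=%s analyte=%s fold=%d sample=%s pred=%.6f true=%.6f",
                variety, analyte, fold_id, sid, pred, true,
            )

    per_spectrum = pd.DataFrame({
        "variety": variety,
        "analyte": analyte,
        "sample_id": groups,
        "temperature_c": temps,
        "y_true": cv.truths,
        "y_pred": cv.predictions,
    })
    model = fit_pls(
        X, y, config.n_components, analyte=analyte,
        metadata={"variety": variety, "n_samples": cv.n_samples,
                  "n_spectra": cv.n_spectra},
    )
    return cv, per_spectrum, model


def run(config: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline; returns the validation report.

    Per variety and analyte: preprocess (after outlier screening), grouped
    LOO-CV at the configured component count, persist the CV table and the
    full-data model, and aggregate the headline report.  Varieties with
    too few samples for the fold structure are skipped with a warning and
    are absent from the report.
    """
    run_dir = Path(config.output_dir)
    (run_dir / "cv").mkdir(parents=True, exist_ok=True)
    (run_dir / "models").mkdir(exist_ok=True)

    fh_log = logging.getLogger(f"{__name__}.run")
    fh_log.setLevel(logging.INFO)
    fh_log.propagate = False
    handler = logging.FileHandler(run_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(message)s"))
    fh_log.handlers = [handler]

    stamp = f"# mustspec config={_config_hash(config)} seed={config.seed}"
    try:
        fh_log.info("run start %s", stamp.lstrip("# "))
        spectra, primary, secondary = _load_inputs(config)
        if config.simulation is not None:
            data_dir = run_dir / "data"
            data_dir.mkdir(exist_ok=True)
            mio.write_spectra(spectra, data_dir / "spectra.csv")
            mio.write_reference(primary, data_dir / "reference_primary.csv")
            if secondary is not None:
                mio.write_reference(secondary, data_dir / "reference_secondary.csv")

        by_variety: dict[str, list] = {}
        for s in spectra:
            by_variety.setdefault(s.variety, []).append(s)

        rows = []
        jobs = [(v, by_variety[v]) for v in sorted(by_variety)]
        if config.pooled:
            jobs.append(("(pooled)", [s for v in sorted(by_variety)
                                      for s in by_variety[v]]))
        for variety, members in jobs:
            try:
                processed, _ = _preprocess_variety(members, config)
                X, groups, temps = _design_matrix(processed, config)
                for analyte in config.analytes:
                    col = f"{analyte}_g_l"
                    y_by_sample = dict(zip(primary["sample_id"], primary[col]))
                    cv, per_spectrum, model = _validate_cell(
                        X, groups, temps, y_by_sample, variety, analyte,
                        config, run_dir, fh_log,
                    )
                    used = primary[primary["sample_id"].isin(set(groups))]
                    vmin = float(used[col].min())
                    vmax = float(used[col].max())
                    rows.append({
                        "variety": variety,
                        "analyte": analyte,
                        "value_min": vmin,
                        "value_max": vmax,
                        "rmsep_g_l": cv.rmsep,
                        "r2_percent": cv.r2_percent,
                        "rmsep_percent_of_range": rmsep_percent_of_range(
                            cv.rmsep, vmin, vmax),
                        "n_samples": cv.n_samples,
                        "n_spectra": cv.n_spectra,
                    })
                    tag = f"{variety.replace(' ', '')}_{analyte}"
                    _write_cv_table(per_spectrum, run_dir / "cv" / f"{tag}.csv", stamp)
                    save_model(model, run_dir / "models" / f"{tag}.json")
            except (ChemometricsError, SpectraError) as exc:
                logger.warning("skipping variety %s: %s", variety, exc)
                fh_log.info("skipped variety=%s reason=%s", variety, exc)

        pooled_rows = [r for r in rows if r["variety"] == "(pooled)"]
        rows = [r for r in rows if r["variety"] != "(pooled)"]
        report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        _write_report(report, run_dir / "report.csv", stamp)
        if pooled_rows:
            _write_report(pd.DataFrame(pooled_rows, columns=REPORT_COLUMNS),
                          run_dir / "pooled_report.csv", stamp)

        if secondary is not None:
            comparison = method_comparison_report(primary, secondary,
                                                  analytes=config.analytes)
            _write_report(comparison, run_dir / "comparison.csv", stamp)
        fh_log.info("run complete rows=%d", len(report))
    finally:
        handler.close()
        fh_log.handlers = []
    return report


def _write_report(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(stamp + "\n")
        df.to_csv(fh, index=False)


def _write_cv_table(df: pd.DataFrame, path: Path, stamp: str) -> None:
    _write_report(df, path, stamp)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a stamped report/CV csv (skips the stamp comment line)."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def method_comparison_report(
    primary: pd.DataFrame,
    secondary: pd.DataFrame,
    analytes=mio.ANALYTES,
) -> pd.DataFrame:
    """Per-analyte OLS agreement table between the two reference methods."""
    shared = set(primary["sample_id"]) & set(secondary["sample_id"])
    if len(shared) < 3:
        raise ChemometricsError(
            f"only {len(shared)} overlapping samples between reference tables"
        )
    rows = []
    for analyte in analytes:
        mc = compare_methods(primary, secondary, analyte)
        rows.append({
            "analyte": analyte,
            "slope": mc.slope,
            "intercept": mc.intercept,
            "r_squared": mc.r_squared,
            "rmse_g_l": mc.rmse,
            "n": mc.n,
        })
    return pd.DataFrame(rows)
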