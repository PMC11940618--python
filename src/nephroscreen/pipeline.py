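"""End-to-end orchestration: viability CSV → PODs → MOS → ranking.

Reads the long-format viability table plus compound annotation and
physicochemical tables, runs vehicle normalization, logistic POD fitting,
media dosimetry, margin-of-safety calculation and classification, and
writes plain-CSV outputs with a JSON ranking summary.  Runs are
deterministic for fixed inputs; outputs are written only after every stage
has completed, so a failed stage leaves no partial files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import datasets
from ._censored import CensoredValue
from .classify import (
    build_confusion_matrix,
    classify_in_vitro,
    compute_metrics,
    rank_cell_sources,
)
from .doseresponse import fit_screen, normalize_to_vehicle
from .dosimetry import CultureSystem, PhysChemProfile, compute_fub_media
from .mos import mos_table

logger = logging.getLogger("nephroscreen")

__all__ = ["PipelineConfig", "read_viability", "read_physchem", "run_pipeline",
           "reproduce_reference_metrics", "PipelineError"]

VIABILITY_COLUMNS = ("cell_source", "drug", "concentration_uM", "replicate", "signal")
PHYSCHEM_COLUMNS = ("drug", "log_kow", "log_kaw", "log_koa", "melting_point_C",
                    "solubility_mg_L", "fub_plasma")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; `default_config()` prints the defaults."""

    viability_csv: str | None = None
    annotations_csv: str | None = None  # None → packaged 12-drug panel
    physchem_csv: str | None = None  # None → fub_media = fub_plasma = 1
    culture_systems: dict[str, dict[str, Any]] = field(default_factory=dict)
    ic_threshold: float = 90.0
    ec_threshold: float = 50.0
    classification_threshold_uM: float = 300.0
    exclusions: tuple[str, ...] = tuple(sorted(datasets.EXCLUDED_DRUGS))
    cmax_basis: str = "max"
    pod_metric: str = "ec50"
    output_dir: str = "out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            logger.warning("ignoring unknown config keys: %s", sorted(unknown))
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "exclusions" in kwargs:
            kwargs["exclusions"] = tuple(kwargs["exclusions"])
        return cls(**kwargs)

    def to_yaml(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["exclusions"] = list(d["exclusions"])
        return yaml.safe_dump(d, sort_keys=True)


def read_viability(path: str | Path) -> pd.DataFrame:
    """Read and validate the long-format viability table."""
    df = pd.read_csv(path)
    missing = [c for c in VIABILITY_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineError(f"[read] viability CSV missing required columns: {missing}")
    extra = [c for c in df.columns if c not in VIABILITY_COLUMNS]
    if extra:
        logger.warning("viability CSV has unknown columns (ignored): %s", extra)
    if df.empty:
        raise PipelineError("[read] no records in viability CSV")
    for col in ("concentration_uM", "signal"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise PipelineError(f"[read] malformed numeric {col!r} at row(s) {list(bad[:5])}")
        df[col] = vals
    neg = df.index[df["concentration_uM"] < 0]
    if len(neg):
        raise PipelineError(f"[read] negative concentration at row(s) {list(neg[:5])}")
    return df


def read_physchem(path: str | Path) -> pd.DataFrame:
    """Read the per-drug physicochemical table (see PHYSCHEM_COLUMNS)."""
    df = pd.read_csv(path)
    missing = [c for c in ("drug", "log_kow", "fub_plasma") if c not in df.columns]
    if missing:
        raise PipelineError(f"[read] physchem CSV missing required columns: {missing}")
    return df


def _fub_maps(
    config: PipelineConfig,
    cell_sources: list[str],
    drugs: list[str],
    physchem: pd.DataFrame | None,
) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """fub_media per (cell source, drug) and fub_plasma per drug."""
    if physchem is None:
        return ({cs: {d: 1.0 for d in drugs} for cs in cell_sources},
                {d: 1.0 for d in drugs})
    pc = physchem.set_index("drug")
    fub_plasma = {}
    profiles = {}
    for d in drugs:
        if d not in pc.index:
            raise PipelineError(f"[dosimetry] no physicochemical row for drug {d!r}")
        row = pc.loc[d]
        kaw = row.get("log_kaw")
        profiles[d] = PhysChemProfile(
            log_kow=float(row["log_kow"]),
            log_kaw=float(kaw) if pd.notna(kaw) else -30.0,
            fub_plasma=float(row["fub_plasma"]),
        )
        fub_plasma[d] = profiles[d].fub_plasma
    fub_media: dict[str, dict[str, float]] = {}
    for cs in cell_sources:
        params = config.culture_systems.get(cs, config.culture_systems.get("default", {}))
        system = CultureSystem(**({"serum_volume_fraction": 0.1} | dict(params)))
        fub_media[cs] = {
            d: compute_fub_media(profiles[d], system).fub_media for d in drugs
        }
    return fub_media, fub_plasma


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write the result bundle to ``output_dir``.

    Returns the bundle: ``pod_table``, ``mos_table``, ``metrics_table``
    (DataFrames), ``ranking`` (ordered list) and ``runlog`` (dict).
    """
    if config.viability_csv is None:
        raise PipelineError("[config] viability_csv is required")

    records = read_viability(config.viability_csv)
    annotations = (
        pd.read_csv(config.annotations_csv)
        if config.annotations_csv
        else datasets.compound_annotations()
    )
    physchem = read_physchem(config.physchem_csv) if config.physchem_csv else None

    try:
        normalized = normalize_to_vehicle(records)
    except Exception as exc:
        raise PipelineError(f"[normalize] {exc}") from exc

    try:
        pods = fit_screen(normalized)
    except Exception as exc:
        raise PipelineError(f"[fit] {exc}") from exc

    cell_sources = sorted(pods["cell_source"].unique())
    drugs = sorted(pods["drug"].unique())

    try:
        fub_media, fub_plasma = _fub_maps(config, cell_sources, drugs, physchem)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[dosimetry] {exc}") from exc

    try:
        mos = mos_table(
            pods, annotations, fub_media, fub_plasma,
            cmax_basis=config.cmax_basis, pod_metric=config.pod_metric,
        )
    except Exception as exc:
        raise PipelineError(f"[mos] {exc}") from exc

    try:
        labels = datasets.in_vivo_labels(annotations)
        metric_rows, ranking_input = [], {}
        for cs in cell_sources:
            sub = pods[pods["cell_source"] == cs]
            calls = {
                r.drug: classify_in_vitro(
                    CensoredValue(r.ec50_pod_uM, bool(r.ec50_censored)),
                    threshold=config.classification_threshold_uM,
                )
                for r in sub.itertuples()
            }
            cm = build_confusion_matrix(calls, labels, exclusions=config.exclusions)
            m = compute_metrics(cm)
            ranking_input[cs] = m
            metric_rows.append(
                {"cell_source": cs, "tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
                 "sensitivity": m.sensitivity, "specificity": m.specificity,
                 "accuracy": m.accuracy, "mcc": m.mcc}
            )
        metrics_df = pd.DataFrame(metric_rows)
        ranking = [
            {"rank": i + 1, "cell_source": name, "mcc": m.mcc, "accuracy": m.accuracy}
            for i, (name, m) in enumerate(rank_cell_sources(ranking_input))
        ]
    except Exception as exc:
        raise PipelineError(f"[classify] {exc}") from exc

    # hash the analytic configuration only: where outputs land is not input
    hashable = "\n".join(
        line for line in config.to_yaml().splitlines() if not line.startswith("output_dir:")
    )
    runlog = {
        "config_sha256": hashlib.sha256(hashable.encode()).hexdigest(),
        "n_records": int(len(records)),
        "n_series_fit": int(len(pods)),
        "n_mos_rows": int(len(mos)),
        "n_cell_sources": len(cell_sources),
        "seed": config.seed,
    }
    logger.info("pipeline complete: %s", runlog)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pods.to_csv(outdir / "pod_table.csv", index=False)
    mos.to_csv(outdir / "mos_table.csv", index=False)
    metrics_df.to_csv(outdir / "metrics_table.csv", index=False)
    (outdir / "ranking.json").write_text(json.dumps(ranking, indent=2, sort_keys=True) + "\n")
    (outdir / "runlog.json").write_text(json.dumps(runlog, indent=2, sort_keys=True) + "\n")

    return {"pod_table": pods, "mos_table": mos, "metrics_table": metrics_df,
            "ranking": ranking, "runlog": runlog}


def reproduce_reference_metrics() -> pd.DataFrame:
    """Classification metrics for all 9 cell sources from the packaged calls.

    Skips curve fitting entirely: uses the packaged in vitro call matrix and
    the 12-drug annotation table, scoring 10 compounds (8 positives, 2
    negatives) per cell source.
    """
    labels = datasets.in_vivo_labels()
    matrix = datasets.call_matrix()
    rows = []
    for cs in datasets.CELL_SOURCES:
        cm = build_confusion_matrix(datasets.calls_for(cs, matrix), labels)
        m = compute_metrics(cm)
        rows.append(
            {"cell_source": cs, "tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
             "sensitivity_pct": m.display_percent("sensitivity"),
             "specificity_pct": m.display_percent("specificity"),
             "accuracy_pct": m.display_percent("accuracy"),
             "mcc": round(m.mcc, 3)}
        )
    return pd.DataFrame(rows)
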