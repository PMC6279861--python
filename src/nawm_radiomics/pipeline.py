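"""End-to-end orchestration: simulate -> extract -> select -> fit ->
evaluate, seeded from a single config, with a hashed run manifest.

One subject-level stratified 7:3 split is generated per cohort and reused
by all three contrasts, so overlapping sample sets never mix train and
test rows of the same subject.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_stats import cohort_table
from .core import ANALYSIS_LABELS, SubjectRecord
from .errors import InvalidArgumentError
from .evaluation import hosmer_lemeshow, roc_auc
from .io import write_cohort
from .modeling import CONTRASTS, ModelResult, build_model, split_train_test
from .selection import FeatureMatrix, SelectionConfig, SelectionResult, run_cascade
from .synthetic import CohortSpec, generate_cohort
from .texture import ExtractionConfig, extract_battery

logger = logging.getLogger(__name__)

_NON_FEATURE_COLUMNS = ("subject_id", "roi_label", "group", "split")


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    train_fraction: float = 0.7
    ci_method: str = "delong"
    hl_groups: int = 10
    write_images: bool = True

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "extraction": self.extraction.to_dict(),
            "selection": self.selection.to_dict(),
            "train_fraction": self.train_fraction,
            "ci_method": self.ci_method,
            "hl_groups": self.hl_groups,
            "write_images": self.write_images,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortSpec.from_dict(d["cohort"])
        if "extraction" in d:
            ext = dict(d["extraction"])
            for key in ("angles", "offsets"):
                if key in ext:
                    ext[key] = tuple(ext[key])
            d["extraction"] = ExtractionConfig(**ext)
        if "selection" in d:
            d["selection"] = SelectionConfig(**d["selection"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def extract_cohort_features(
    records: list[SubjectRecord], config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Feature battery for every analysis ROI of a cohort; one row per
    (subject, ROI class)."""
    config = config or ExtractionConfig()
    rows = []
    for rec in records:
        for mask in rec.analysis_masks:
            feats = extract_battery(rec.baseline, mask, config)
            row = {"subject_id": rec.subject_id, "roi_label": mask.label,
                   "group": rec.group}
            row.update(feats)
            rows.append(row)
    return pd.DataFrame(rows)


def assign_subject_split(
    features: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> pd.DataFrame:
    """Add a subject-level train/test column, stratified by group."""
    subjects = features.drop_duplicates("subject_id")[["subject_id", "group"]]
    assignment = split_train_test(
        subjects["group"].to_numpy(), train_fraction=train_fraction, seed=seed
    )
    mapping = dict(zip(subjects["subject_id"], assignment))
    out = features.copy()
    out["split"] = out["subject_id"].map(mapping)
    return out


def contrast_matrix(features: pd.DataFrame, contrast: str) -> FeatureMatrix:
    """Slice the per-ROI feature table into the binary FeatureMatrix of
    one contrast (second class of the pair is coded 1)."""
    if contrast not in CONTRASTS:
        raise InvalidArgumentError(
            f"contrast must be one of {sorted(CONTRASTS)}, got {contrast!r}"
        )
    neg, pos = CONTRASTS[contrast]
    sub = features[features["roi_label"].isin([neg, pos])].reset_index(drop=True)
    feature_cols = [c for c in sub.columns if c not in _NON_FEATURE_COLUMNS]
    return FeatureMatrix(
        features=sub[feature_cols],
        labels=(sub["roi_label"] == pos).astype(int),
        split=sub["split"],
    )


def evaluate_model(
    result: ModelResult, ci_method: str = "delong", hl_groups: int = 10
) -> dict:
    """ROC on both splits plus Hosmer–Lemeshow calibration on the
    training fit."""
    roc_train = roc_auc(result.prob_train, result.y_train, ci_method=ci_method)
    roc_test = roc_auc(result.prob_test, result.y_test, ci_method=ci_method)
    try:
        hl = hosmer_lemeshow(
            result.prob_train.to_numpy(), result.y_train.to_numpy(), groups=hl_groups
        )
        hl_payload = hl.to_dict()
    except InvalidArgumentError as exc:
        # near-perfect fits collapse the risk deciles; calibration is
        # then undefined rather than silently reported
        hl_payload = {"statistic": None, "df": None, "p_value": None,
                      "degenerate": str(exc)}
    report = {
        "train": roc_train.to_dict(),
        "test": roc_test.to_dict(),
        "hosmer_lemeshow": hl_payload,
    }
    result.evaluation = report
    return report


def run_contrast(
    features: pd.DataFrame,
    contrast: str,
    selection_config: SelectionConfig | None = None,
    seed: int = 0,
    ci_method: str = "delong",
    hl_groups: int = 10,
) -> tuple[SelectionResult, ModelResult, dict]:
    """Selection cascade, logistic fit, and evaluation for one contrast."""
    fm = contrast_matrix(features, contrast)
    sel = run_cascade(fm, selection_config, seed=seed)
    result = build_model(fm.drop_missing(), sel, contrast=contrast)
    report = evaluate_model(result, ci_method=ci_method, hl_groups=hl_groups)
    return sel, result, report


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write every artifact; returns the run
    manifest (also written as ``run_manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "artifacts": [],
        "status": "running",
    }
    stage = "simulate"
    try:
        records = generate_cohort(config.cohort)
        if config.write_images:
            write_cohort(records, outdir / "cohort")
            manifest["artifacts"].append("cohort/manifest.csv")
        stage = "extract"
        features = extract_cohort_features(records, config.extraction)
        features = assign_subject_split(
            features, train_fraction=config.train_fraction, seed=config.cohort.seed
        )
        features.to_csv(outdir / "features.csv", index=False)
        manifest["artifacts"].append("features.csv")
        stage = "cohort-table"
        meta_rows = []
        for rec in records:
            row = {"subject_id": rec.subject_id, "group": rec.group}
            row.update(rec.metadata)
            meta_rows.append(row)
        table1 = cohort_table(pd.DataFrame(meta_rows))
        table1.to_csv(outdir / "table1.csv", index=False)
        manifest["artifacts"].append("table1.csv")
        for contrast in CONTRASTS:
            stage = f"select/{contrast}"
            sel, result, report = run_contrast(
                features,
                contrast,
                selection_config=config.selection,
                seed=config.cohort.seed,
                ci_method=config.ci_method,
                hl_groups=config.hl_groups,
            )
            sel_payload = sel.to_dict()
            sel_payload["config_hash"] = manifest["config_hash"]
            _write_json(outdir / f"selection_{contrast}.json", sel_payload)
            model_payload = result.model.to_dict()
            model_payload["config_hash"] = manifest["config_hash"]
            _write_json(outdir / f"model_{contrast}.json", model_payload)
            report["config_hash"] = manifest["config_hash"]
            _write_json(outdir / f"report_{contrast}.json", report)
            manifest["artifacts"] += [
                f"selection_{contrast}.json",
                f"model_{contrast}.json",
                f"report_{contrast}.json",
            ]
            manifest[f"{contrast}_test_auc"] = report["test"]["auc"]
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(outdir / "run_manifest.json", manifest)
        raise
    manifest["status"] = "complete"
    manifest["artifact_hashes"] = {
        name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()[:16]
        for name in manifest["artifacts"]
        if (outdir / name).is_file()
    }
    _write_json(outdir / "run_manifest.json", manifest)
    return manifest


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
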