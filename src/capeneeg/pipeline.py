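"""Staged analysis pipeline: simulate -> features -> classify -> evaluate -> cohort stats.

Each stage is a plain function over a :class:`PipelineConfig`; the CLI and
the numbered analysis drivers are thin wrappers around these.  Stages are
deterministic given the config and its seed, read their inputs from the
previous stage's output files, and write CSVs with a ``#``-prefixed
provenance header (package version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .capen import CApEnParams
from .cohort_stats import (
    REGRESSION_CAPEN_CELLS,
    baseline_table,
    improvement_table,
    mgos_regression,
    regression_frame,
)
from .errors import PrerequisiteError
from .features import features_to_frame, pair_features, summary_frame
from .io import read_cohort_csv, read_recording, write_cohort_csv, write_recording
from .montage import CONDITIONS, MontageMap
from .prognosis import DEFAULT_CUTOFF, classify_many, confusion, roc
from .synthetic import CohortConfig, calibrate_knob, gen_cohort_table, gen_patient_recordings


@dataclass
class PipelineConfig:
    """Everything that can alter a pipeline number, in one place."""

    out_dir: str = "results/pipeline"
    recordings_dir: str | None = None  # default: <out_dir>/recordings
    recording_format: str = "edf"  # edf | tabular
    capen: CApEnParams = field(default_factory=CApEnParams)
    cutoff: float = DEFAULT_CUTOFF
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if self.recordings_dir is None:
            self.recordings_dir = str(Path(self.out_dir) / "recordings")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "capen" in raw:
            raw["capen"] = CApEnParams(**raw["capen"])
        if "cohort" in raw:
            cohort = dict(raw["cohort"])
            if "knob_bounds" in cohort:
                cohort["knob_bounds"] = tuple(cohort["knob_bounds"])
            raw["cohort"] = CohortConfig(**cohort)
        cfg = cls(**raw)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance(self) -> list[str]:
        return [
            f"capeneeg {__version__}",
            f"seed={self.seed}",
            f"config_hash={self.config_hash()}",
        ]


def _write_csv(path: Path, df: pd.DataFrame, config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in config.provenance():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path, producer: str) -> pd.DataFrame:
    if not path.exists():
        raise PrerequisiteError(f"{path} not found; run the '{producer}' stage first")
    return pd.read_csv(path, comment="#")


def cmd_simulate(config: PipelineConfig) -> pd.DataFrame:
    """Generate the synthetic cohort: metadata CSV plus per-condition recordings."""
    cohort_cfg = CohortConfig(**{**asdict(config.cohort), "seed": config.seed})
    calibration = calibrate_knob(cohort_cfg, params=config.capen)
    table = gen_cohort_table(cohort_cfg, calibration)
    out = Path(config.out_dir)
    rec_dir = Path(config.recordings_dir)
    rec_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".edf" if config.recording_format == "edf" else ".csv"
    for _, row in table.iterrows():
        for cond, rec in gen_patient_recordings(cohort_cfg, row).items():
            write_recording(
                rec_dir / f"{row['patient_id']}_{cond}{suffix}",
                rec,
                config.recording_format,
            )
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(out / "cohort.csv", table, config.provenance())
    return table


def cmd_features(config: PipelineConfig, pairs=None) -> pd.DataFrame:
    """Compute the pair x condition C-ApEn table and per-patient D values."""
    out = Path(config.out_dir)
    cohort_path = out / "cohort.csv"
    if not cohort_path.exists():
        raise PrerequisiteError(f"{cohort_path} not found; run the 'simulate' stage first")
    table = read_cohort_csv(cohort_path)
    rec_dir = Path(config.recordings_dir)
    suffix = ".edf" if config.recording_format == "edf" else ".csv"
    all_feats = []
    for _, row in table.iterrows():
        recordings = {}
        for cond in CONDITIONS:
            path = rec_dir / f"{row['patient_id']}_{cond}{suffix}"
            if not path.exists():
                raise PrerequisiteError(
                    f"{path} not found; run the 'simulate' stage first"
                )
            recordings[cond] = read_recording(
                path, config.recording_format, condition=cond,
                patient_id=str(row["patient_id"]),
            )
        montage = MontageMap(row["affected_side"])
        all_feats.append(pair_features(recordings, montage, config.capen, pairs=pairs))
    _write_csv(out / "features.csv", features_to_frame(all_feats), config)
    _write_csv(out / "summary.csv", summary_frame(all_feats), config)
    return summary_frame(all_feats)


def cmd_classify(config: PipelineConfig) -> pd.DataFrame:
    """Apply the fixed-cutoff classifier to the D summary."""
    out = Path(config.out_dir)
    summary = _read_csv(out / "summary.csv", "features")
    preds = summary.copy()
    preds["predicted_improvement"] = classify_many(preds["D"], config.cutoff)
    _write_csv(out / "predictions.csv", preds, config)
    return preds


def cmd_evaluate(config: PipelineConfig) -> dict:
    """Confusion summaries per group and pooled ROC analysis."""
    out = Path(config.out_dir)
    preds = _read_csv(out / "predictions.csv", "classify")
    cohort = read_cohort_csv(out / "cohort.csv")
    merged = preds.merge(cohort, on="patient_id", validate="one_to_one")
    rows = []
    for label, sub in [("pooled", merged), *merged.groupby("group")]:
        cm = confusion(sub["predicted_improvement"], sub["improved"])
        rows.append(
            {"group": label, "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
             "sensitivity": cm.sensitivity, "specificity": cm.specificity}
        )
    conf_df = pd.DataFrame(rows)
    roc_res = roc(merged["D"].to_numpy(), merged["improved"].to_numpy())
    roc_df = pd.DataFrame(
        {"threshold": roc_res.thresholds, "sensitivity": roc_res.sensitivity,
         "specificity": roc_res.specificity}
    )
    _write_csv(out / "confusion.csv", conf_df, config)
    _write_csv(out / "roc.csv", roc_df, config)
    (out / "roc_summary.yaml").write_text(
        yaml.safe_dump({"auc": float(roc_res.auc), "youden_cutoff": float(roc_res.youden_cutoff)})
    )
    return {"confusion": conf_df, "roc": roc_res}


def cmd_cohort_stats(config: PipelineConfig, dependent: str = "mgos") -> dict:
    """Baseline comparisons, improvement rates, and the mGOS regression table."""
    out = Path(config.out_dir)
    cohort = read_cohort_csv(out / "cohort.csv")
    features = _read_csv(out / "features.csv", "features")
    base = baseline_table(cohort)
    improve = improvement_table(cohort)

    wide = features.pivot_table(
        index="patient_id", columns=["pair", "condition"], values="capen"
    )
    design = pd.DataFrame(index=wide.index)
    for pair, cond in REGRESSION_CAPEN_CELLS:
        if (pair, cond) in wide.columns:
            design[f"{pair}@{cond}"] = wide[(pair, cond)]
    meta = cohort.set_index("patient_id")
    design["sex"] = (meta["sex"] == "female").astype(float)
    design["age"] = meta["age"].astype(float)
    design["duration"] = meta["duration_days"].astype(float)
    design["lesion"] = (meta["lesion"] == "hemorrhage").astype(float)
    design["mgos"] = meta["mgos"].astype(float)
    design["improved"] = meta["improved"].astype(float)
    design = design.dropna()
    predictors = [c for c in design.columns if c not in ("mgos", "improved")]
    reg = regression_frame(mgos_regression(design, dependent=dependent, predictors=predictors))

    _write_csv(out / "baseline.csv", base, config)
    _write_csv(out / "improvement.csv", improve, config)
    _write_csv(out / "regression.csv", reg, config)
    return {"baseline": base, "improvement": improve, "regression": reg}


def evaluate_synthetic_cohort(
    cohort_cfg: CohortConfig,
    params: CApEnParams | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> dict:
    """In-memory end-to-end run: cohort -> D estimates -> classifier metrics.

    Computes only the Cu-FPu pair under the two conditions entering D, so an
    85-patient cohort evaluates in well under a minute.  Returns the cohort
    table (with a ``D`` column added), the confusion summary at *cutoff* and
    the pooled ROC result.
    """
    from .features import difference_statistic
    from .montage import pair_catalog

    params = params or CApEnParams()
    calibration = calibrate_knob(cohort_cfg, params=params)
    table = gen_cohort_table(cohort_cfg, calibration)
    d_pair = [p for p in pair_catalog() if p.name == "Cu-FPu"]
    d_values = []
    for _, row in table.iterrows():
        recs = gen_patient_recordings(cohort_cfg, row)
        recs = {c: recs[c] for c in ("pain_unaffected", "closed_eyes")}
        feats = pair_features(recs, MontageMap(row["affected_side"]), params, pairs=d_pair)
        d_values.append(difference_statistic(feats))
    table = table.assign(D=d_values)
    preds = classify_many(table["D"], cutoff)
    cm = confusion(preds, table["improved"])
    roc_res = roc(table["D"].to_numpy(), table["improved"].to_numpy())
    return {"table": table, "confusion": cm, "roc": roc_res, "calibration": calibration}


def run_all(config: PipelineConfig) -> dict:
    """simulate -> features -> classify -> evaluate -> cohort-stats."""
    cmd_simulate(config)
    cmd_features(config)
    cmd_classify(config)
    evaluation = cmd_evaluate(config)
    tables = cmd_cohort_stats(config)
    return {**evaluation, **tables}
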