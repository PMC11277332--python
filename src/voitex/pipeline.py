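"""Pipeline orchestration: simulate -> extract -> reduce -> compare.

Each stage is a plain function over files so runs are resumable and every
artifact is reproducible from the configuration; the config (and its hash)
is echoed into a run log and into the header comment of every CSV output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import glcm as _glcm
from .io import (
    load_manifest,
    manifest_to_frame,
    read_feature_table,
    read_mask,
    read_nifti_volume,
    summarize_manifest,
    write_feature_table,
)
from .reduction import reduce_distances
from .stats import (
    chi_square_test,
    compare_all_features,
    comparison_to_frame,
    summarize_groups,
)
from .synthetic import SyntheticCohortConfig, generate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    levels: int = 128
    distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    angle_mode: str = "all"            # "all" or one of "0","45","90","135"
    pooling_mode: str = "pooled"       # or "per_slice_mean"
    log_base: float | None = None      # None = natural log
    rho_threshold: float = 0.8
    alpha: float = 0.05
    dunn_adjust: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if not self.distances or any(d < 1 for d in self.distances):
            raise ValueError("distances must be positive")
        if self.pooling_mode not in ("pooled", "per_slice_mean"):
            raise ValueError(f"unknown pooling_mode {self.pooling_mode!r}")
        if self.angle_mode != "all" and self.angle_mode not in ("0", "45", "90", "135"):
            raise ValueError(f"unknown angle_mode {self.angle_mode!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.dunn_adjust not in ("none", "bonferroni", "holm"):
            raise ValueError(f"unknown dunn_adjust {self.dunn_adjust!r}")

    @property
    def angles(self) -> tuple[int, ...]:
        if self.angle_mode == "all":
            return _glcm.ALL_ANGLES
        return (int(self.angle_mode),)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distances"] = list(self.distances)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "distances" in raw:
            raw["distances"] = tuple(raw["distances"])
        return cls(**raw)


def run_simulate(cfg: PipelineConfig, out_dir: str | os.PathLike,
                 cohort_cfg: SyntheticCohortConfig | None = None) -> Path:
    """Generate the synthetic cohort on disk; returns the manifest path."""
    try:
        return generate_cohort(cohort_cfg or SyntheticCohortConfig(), out_dir, cfg.seed)
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc


def run_extract(
    manifest_path: str | os.PathLike,
    data_dir: str | os.PathLike,
    out_csv: str | os.PathLike,
    cfg: PipelineConfig,
) -> Path:
    """Extract the 11 x len(distances) feature columns for every patient.

    Volumes/masks are looked up as '<id>_ct.nii.gz' / '<id>_mask.nii.gz'
    under ``data_dir``.  Per-patient failures are collected and reported
    together; any failure raises.
    """
    data_dir = Path(data_dir)
    records = load_manifest(manifest_path)
    rows, flag_rows, failures = [], [], []
    for rec in records:
        try:
            vol = read_nifti_volume(data_dir / f"{rec.patient_id}_ct.nii.gz")
            mask = read_mask(data_dir / f"{rec.patient_id}_mask.nii.gz", vol)
            tv = _glcm.extract_texture_vector(
                vol, mask, patient_id=rec.patient_id,
                distances=cfg.distances, n_levels=cfg.levels,
                angles=cfg.angles, log_base=cfg.log_base, pooling=cfg.pooling_mode,
            )
        except Exception as exc:
            logger.error("patient %s failed: %s", rec.patient_id, exc)
            failures.append(f"{rec.patient_id}: {exc}")
            continue
        logger.info("patient %s: VOI %d voxels, %d distances",
                    rec.patient_id, mask.n_voxels, len(cfg.distances))
        rows.append({"patient_id": rec.patient_id, "group": rec.group, **tv.as_columns()})
        for (param, d), reason in tv.degenerate_flags.items():
            flag_rows.append({"patient_id": rec.patient_id, "parameter": param,
                              "distance": d, "reason": reason})
    if failures:
        raise StageError("extract", "; ".join(failures))
    out_csv = Path(out_csv)
    write_feature_table(rows, out_csv, header_comment=f"config_hash={cfg.config_hash()}")
    flags_path = out_csv.with_name(out_csv.stem + "_flags.csv")
    pd.DataFrame(flag_rows, columns=["patient_id", "parameter", "distance", "reason"]).to_csv(
        flags_path, index=False
    )
    return out_csv


def run_reduce(
    features_csv: str | os.PathLike,
    out_csv: str | os.PathLike,
    report_json: str | os.PathLike,
    cfg: PipelineConfig,
) -> Path:
    """Collapse distance columns per parameter; writes reduced CSV + report."""
    fm = read_feature_table(features_csv)
    try:
        reduced, report = reduce_distances(fm, threshold=cfg.rho_threshold)
    except Exception as exc:
        raise StageError("reduce", str(exc)) from exc
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    with open(out_csv, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\n")
        reduced.to_csv(fh, index=False, float_format="%.17g")
    report.to_json(report_json)
    logger.info("reduction: %d feature columns",
                sum(len(pr.columns()) for pr in report.parameters.values()))
    return out_csv


def run_compare(
    reduced_csv: str | os.PathLike,
    manifest_path: str | os.PathLike,
    out_dir: str | os.PathLike,
    cfg: PipelineConfig,
) -> dict:
    """Group comparison of age + reduced features; writes tables and JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reduced = read_feature_table(reduced_csv)
    manifest = manifest_to_frame(load_manifest(manifest_path))
    unknown = set(reduced["patient_id"]) - set(manifest["patient_id"])
    if unknown:
        raise StageError("compare", f"patients not in manifest: {sorted(unknown)}")
    df = manifest.merge(reduced.drop(columns=["group"], errors="ignore"), on="patient_id")

    feature_cols = [c for c in reduced.columns if c not in ("patient_id", "group")]
    variables = ["age", *feature_cols]
    try:
        results = compare_all_features(
            df, variables=variables, alpha=cfg.alpha, dunn_adjust=cfg.dunn_adjust
        )
    except Exception as exc:
        raise StageError("compare", str(exc)) from exc

    kw_frame = comparison_to_frame(results)
    kw_frame.to_csv(out_dir / "kruskal_wallis.csv", index=False)
    with open(out_dir / "dunn_pairwise.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                r.variable: [
                    {"pair": [d.group_a, d.group_b], "z": d.z,
                     "p_raw": d.p_raw, "p_adjusted": d.p_adjusted}
                    for d in r.dunn
                ]
                for r in results if r.dunn
            },
            fh, indent=2,
        )

    summary = summarize_groups(df, variables)
    summary.to_csv(out_dir / "group_summary.csv", index=False)

    # categorical manifest fields vs group (chi-square), when non-constant
    chi_rows = []
    for cat in ("sex", "tissue", "grade"):
        table = pd.crosstab(df[cat], df["group"])
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        res = chi_square_test(table.to_numpy())
        chi_rows.append({"variable": cat, "chi2": res.chi2, "df": res.df,
                         "p_value": res.p_value, "low_expected": res.low_expected})
    pd.DataFrame(chi_rows, columns=["variable", "chi2", "df", "p_value", "low_expected"]).to_csv(
        out_dir / "chi_square.csv", index=False
    )

    summarize_manifest(load_manifest(manifest_path)).to_csv(
        out_dir / "manifest_summary.csv", index=False
    )
    significant = [r.variable for r in results if r.significant]
    logger.info("compare: %d/%d variables significant at alpha=%g",
                len(significant), len(results), cfg.alpha)
    return {"results": results, "significant": significant, "summary": summary}


def run_all(
    cfg: PipelineConfig,
    run_dir: str | os.PathLike,
    simulate: bool = True,
    cohort_cfg: SyntheticCohortConfig | None = None,
    manifest_path: str | os.PathLike | None = None,
    data_dir: str | os.PathLike | None = None,
    resume: bool = False,
) -> dict:
    """End-to-end run into a single directory with a config echo and log.

    With ``resume=True`` a stage whose outputs already exist is skipped.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "config.json", "w", encoding="utf-8") as fh:
        json.dump({"hash": cfg.config_hash(), **cfg.to_dict()}, fh, indent=2)

    if simulate:
        data_dir = run_dir / "cohort"
        manifest_path = data_dir / "manifest.csv"
        if not (resume and manifest_path.exists()):
            run_simulate(cfg, data_dir, cohort_cfg)
    if manifest_path is None or data_dir is None:
        raise StageError("extract", "manifest_path and data_dir required when not simulating")

    features_csv = run_dir / "features.csv"
    if not (resume and features_csv.exists()):
        run_extract(manifest_path, data_dir, features_csv, cfg)

    reduced_csv = run_dir / "reduced.csv"
    report_json = run_dir / "reduction_report.json"
    if not (resume and reduced_csv.exists()):
        run_reduce(features_csv, reduced_csv, report_json, cfg)

    compare_dir = run_dir / "comparison"
    out = run_compare(reduced_csv, manifest_path, compare_dir, cfg)
    out["run_dir"] = run_dir
    return out
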