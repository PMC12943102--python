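"""End-to-end orchestration: registry -> descriptors -> drug-likeness ->
bioactivity -> food profiling, with a machine-readable run manifest.

Stages are pure functions of (inputs, config); re-running a stage on
unchanged inputs reproduces byte-identical outputs. A stage whose inputs are
absent is marked ``skipped``; a stage that raises is marked ``failed``, and
independent downstream stages still run. Report numbers are written at full
precision; any rounding (e.g. percentages) is left to presentation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, bioactivity, druglikeness, food, registry
from .descriptors import RuleThresholds, descriptor_table
from .errors import ConfigError
from .food import TierConfig
from .registry import OutlierConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    output_dir: str
    compound_tables: list[dict] = field(default_factory=list)  # {path, source_tag}
    activity_table: str | None = None
    food_table: str | None = None
    external_scores: str | None = None
    external_scores_key: str = "name"
    column_maps: dict = field(default_factory=dict)
    rule_thresholds: RuleThresholds = field(default_factory=RuleThresholds)
    tier_config: TierConfig = field(default_factory=TierConfig)
    outlier_config: OutlierConfig = field(default_factory=OutlierConfig)
    welch: bool = True
    seed: int = 0
    log_level: str = "INFO"


def validate_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration, collecting every error at once."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["configuration root must be a mapping"])
    if "output_dir" not in raw:
        errors.append("missing required field: output_dir")
    for i, entry in enumerate(raw.get("compound_tables", [])):
        if "path" not in entry or "source_tag" not in entry:
            errors.append(f"compound_tables[{i}] needs 'path' and 'source_tag'")
        elif not Path(entry["path"]).exists():
            errors.append(f"compound_tables[{i}].path does not exist: {entry['path']}")
    for key in ("activity_table", "food_table", "external_scores"):
        p = raw.get(key)
        if p is not None and not Path(p).exists():
            errors.append(f"{key} does not exist: {p}")
    kwargs = {}
    for fld, cls in (
        ("rule_thresholds", RuleThresholds),
        ("tier_config", TierConfig),
        ("outlier_config", OutlierConfig),
    ):
        if fld in raw:
            try:
                kwargs[fld] = cls(**raw[fld])
            except (TypeError, ValueError) as err:
                errors.append(f"{fld}: {err}")
    if errors:
        raise ConfigError(errors)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    kwargs.update({k: v for k, v in raw.items() if k in known and k not in kwargs})
    return RunConfig(**kwargs)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    def record(stage: str, status: str, **counts):
        manifest["stages"][stage] = {"status": status, **counts}

    # --- registry ---------------------------------------------------------
    reconciled = None
    try:
        if not config.compound_tables:
            record("registry", "skipped")
        else:
            collections = [
                registry.load_compound_table(
                    entry["path"],
                    entry["source_tag"],
                    column_map=config.column_maps.get(entry["source_tag"]),
                )
                for entry in config.compound_tables
            ]
            result = registry.reconcile(collections)
            reconciled = result.records
            frame = registry.records_to_frame(reconciled)
            frame.to_csv(outdir / "compounds_reconciled.csv", index=False)
            registry.coverage_summary(reconciled).to_csv(
                outdir / "coverage_summary.csv", index=False
            )
            pd.DataFrame(
                [dataclasses.asdict(c) for c in result.conflicts]
            ).to_csv(outdir / "merge_conflicts.csv", index=False)
            record(
                "registry",
                "ok",
                rows_in=sum(len(c) for c in collections),
                rows_out=len(reconciled),
                conflicts=len(result.conflicts),
                skeleton_matches=len(result.skeleton_matches),
            )
    except Exception as err:  # stage isolation: later stages still run
        logger.exception("registry stage failed")
        record("registry", "failed", error=str(err))

    # --- descriptors + rule compliance ------------------------------------
    desc = None
    try:
        if reconciled is None:
            record("descriptors", "skipped")
        else:
            frame = registry.records_to_frame(reconciled)
            desc = descriptor_table(frame, thresholds=config.rule_thresholds)
            desc.to_csv(outdir / "descriptors.csv", index=False)
            mw_lookup = {
                r["compound_id"]: r["mw"]
                for _, r in desc.iterrows()
                if r["parse_status"] == "ok"
            }
            outliers = registry.flag_mass_outliers(
                reconciled, mw_lookup, config.outlier_config
            )
            pd.DataFrame(
                outliers, columns=["compound_id", "z_score", "flagged"]
            ).to_csv(outdir / "mass_outliers.csv", index=False)
            record(
                "descriptors",
                "ok",
                rows_in=len(frame),
                rows_out=len(desc),
                parse_errors=int((desc["parse_status"] == "error").sum()),
            )
    except Exception as err:
        logger.exception("descriptors stage failed")
        record("descriptors", "failed", error=str(err))

    # --- drug-likeness -----------------------------------------------------
    try:
        if reconciled is None:
            record("druglikeness", "skipped")
        else:
            frame = registry.records_to_frame(reconciled)
            scores = druglikeness.score_table(frame)
            if config.external_scores:
                merged, _report = druglikeness.ingest_scores(
                    config.external_scores,
                    frame,
                    key=config.external_scores_key,
                )
                scores = scores.merge(
                    merged[["compound_id", "dw_score"]], on="compound_id", how="left"
                )
            scores.to_csv(outdir / "druglikeness_scores.csv", index=False)
            qed_scores = scores["qed"].dropna()
            summaries = {}
            if len(qed_scores):
                summaries["qed"] = dataclasses.asdict(druglikeness.summarize(qed_scores))
            if "dw_score" in scores and scores["dw_score"].notna().any():
                summaries["dw_score"] = dataclasses.asdict(
                    druglikeness.summarize(scores["dw_score"])
                )
            (outdir / "score_summaries.json").write_text(
                json.dumps(summaries, indent=1, sort_keys=True)
            )
            metric_cols = scores.drop(columns=["complete_structure"])
            if desc is not None:
                metric_cols = metric_cols.merge(
                    desc[desc["parse_status"] == "ok"][
                        ["compound_id", "mw", "logp", "hbd", "hba_lipinski", "tpsa"]
                    ],
                    on="compound_id",
                    how="left",
                )
            corr, _insufficient = druglikeness.correlation_matrix(
                metric_cols.drop(columns=["compound_id"])
            )
            corr.to_csv(outdir / "correlation_matrix.csv")
            record(
                "druglikeness",
                "ok",
                rows_in=len(frame),
                rows_out=len(scores),
                qed_complete=int(scores["complete_structure"].sum()),
            )
    except Exception as err:
        logger.exception("druglikeness stage failed")
        record("druglikeness", "failed", error=str(err))

    # --- bioactivity --------------------------------------------------------
    try:
        if config.activity_table is None:
            record("bioactivity", "skipped")
        else:
            raw = pd.read_csv(config.activity_table)
            kept, rejections = bioactivity.filter_records(raw)
            collapsed = bioactivity.collapse_best(bioactivity.add_pchembl(kept))
            collapsed.to_csv(outdir / "activities_collapsed.csv", index=False)
            rejections.to_csv(outdir / "activity_rejections.csv", index=False)
            summaries = []
            for cls, sub in collapsed.groupby("cls"):
                per_target = bioactivity.target_summaries(sub)
                per_target.insert(0, "cls", cls)
                summaries.append(per_target)
            pd.concat(summaries).to_csv(outdir / "target_summaries.csv", index=False)
            comparison = bioactivity.compare_classes(collapsed, welch=config.welch)
            (outdir / "class_comparison.json").write_text(
                json.dumps(dataclasses.asdict(comparison), indent=1, sort_keys=True)
            )
            record(
                "bioactivity",
                "ok",
                rows_in=len(raw),
                rows_kept=len(kept),
                rows_out=len(collapsed),
                rejections=int(rejections["n_rejected"].sum()),
            )
    except Exception as err:
        logger.exception("bioactivity stage failed")
        record("bioactivity", "failed", error=str(err))

    # --- food mapping -------------------------------------------------------
    try:
        if config.food_table is None:
            record("food", "skipped")
        else:
            raw = pd.read_csv(config.food_table)
            kept, excluded = food.standardize_table(raw)
            food.per_pair_stats(kept).to_csv(outdir / "food_pair_stats.csv", index=False)
            totals = food.food_totals(kept)
            tiers = food.tier_table(totals, config.tier_config)
            tiers.to_csv(outdir / "food_totals.csv", index=False)
            profiles = pd.DataFrame(
                [dataclasses.asdict(p) for p in food.group_profiles(kept)]
            )
            profiles.to_csv(outdir / "group_profiles.csv", index=False)
            excluded.to_csv(outdir / "food_exclusions.csv", index=False)
            record(
                "food",
                "ok",
                rows_in=len(raw),
                rows_out=len(kept),
                rejections=len(excluded),
            )
    except Exception as err:
        logger.exception("food stage failed")
        record("food", "failed", error=str(err))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


__all__ = ["RunConfig", "validate_config", "run_all"]
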