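"""End-to-end orchestration: ingest -> segment -> densitometry -> cohort stats.

A run is driven by a single :class:`PipelineConfig` (loadable from YAML) that
points at a per-case manifest: one row per case with a volume path, an
optional precomputed mask path (which bypasses automatic segmentation
unchanged), and the cohort metadata columns.  Outputs are plain CSV/JSON
files with no timestamps, so a fixed config and seed reproduce byte-identical
results.

Exit-status convention (used by the CLI): 0 = all cases processed,
2 = some cases failed and were skipped, 1 = hard error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CaseRecord, apply_inclusion_criteria, assess_normality,
                     compare_groups, dataframe_to_records, subgroup_summary,
                     summarize_group)
from .densitometry import summarize_case
from .io_ct import LungDensError, read_ct_volume, read_mask
from .segmentation import SegmentationParams, remove_airways, segment_lungs

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    manifest: str | pd.DataFrame = ""
    cutoffs: tuple[float, float] = (-950.0, -910.0)
    fraction: float = 0.15
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    alpha: float = 0.05
    t_variant: str = "pooled"
    percentile_convention: str = "nearest_rank"
    stats_mode: str = "auto"
    out_dir: str = "lungdens_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if len(self.cutoffs) == 0 or any(c <= -1024 for c in self.cutoffs):
            raise LungDensError("cutoffs must be non-empty and above -1024 HU")
        if not 0.0 < self.fraction < 1.0:
            raise LungDensError("percentile fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(raw["cutoffs"])
        return cls(segmentation=seg, **raw)

    def config_hash(self) -> str:
        """Stable hash of the scientific settings (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        if isinstance(d.get("manifest"), pd.DataFrame):  # pragma: no cover
            d["manifest"] = "<inline>"
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


@dataclass
class RunReport:
    n_processed: int
    n_failed: int
    n_included: int
    outputs: dict
    exit_code: int


_ENDPOINTS = ["laa950", "laa910", "perc15", "volume_ml"]
_DEMOGRAPHIC_VARS = ["age", "height_cm", "weight_kg", "pmi_days"]


def _comparison_rows(records, alpha, t_variant, mode) -> list[dict]:
    asphyxia = [r for r in records if not r.is_control]
    control = [r for r in records if r.is_control]
    rows = []

    def one_row(variable, a_vals, c_vals):
        a = np.asarray(a_vals, float)
        c = np.asarray(c_vals, float)
        res = compare_groups(a, c, mode=mode, alpha=alpha, t_variant=t_variant)
        row = {"variable": variable, "method": res.method, "variant": res.variant,
               "statistic": res.statistic, "p_value": res.p_value,
               "n_asphyxia": res.n_per_group[0], "n_control": res.n_per_group[1]}
        for prefix, summ in zip(("asphyxia", "control"), res.group_summaries):
            for k, v in summ.items():
                if k != "n":
                    row[f"{prefix}_{k}"] = v
        return row

    for var in _DEMOGRAPHIC_VARS:
        rows.append(one_row(var,
                            [getattr(r, var) for r in asphyxia],
                            [getattr(r, var) for r in control]))
    for ep in _ENDPOINTS:
        rows.append(one_row(ep,
                            [getattr(r.densitometry, ep) for r in asphyxia
                             if r.densitometry is not None],
                            [getattr(r.densitometry, ep) for r in control
                             if r.densitometry is not None]))
    return rows


def render_summary_table(records, alpha: float = 0.05, t_variant: str = "pooled",
                         mode: str = "auto") -> pd.DataFrame:
    """Two-group summary rows (with p) followed by subgroup rows (without p)."""
    main = pd.DataFrame(_comparison_rows(records, alpha, t_variant, mode))
    sub = subgroup_summary(records)
    if not sub.empty:
        sub = sub.rename(columns={"subgroup": "variable"})
        sub.insert(1, "section", "subgroup")
        main.insert(1, "section", "two_group")
        return pd.concat([main, sub], ignore_index=True)
    main.insert(1, "section", "two_group")
    return main


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = (config.manifest if isinstance(config.manifest, pd.DataFrame)
                else pd.read_csv(config.manifest))
    if manifest.empty:
        raise LungDensError("empty manifest")

    case_rows, provenance, failures = [], {}, []
    for _, row in manifest.iterrows():
        case_id = str(row["case_id"])
        try:
            vol = read_ct_volume(row["volume_path"])
            mask_path = row.get("mask_path")
            if isinstance(mask_path, str) and mask_path:
                mask = read_mask(mask_path)   # external masks bypass segmentation
                provenance[case_id] = "supplied_mask"
            else:
                mask = segment_lungs(vol, config.segmentation)
                mask = remove_airways(vol, mask, config.segmentation)
                provenance[case_id] = "auto_segmentation"
            dens = summarize_case(vol, mask, config.cutoffs, config.fraction,
                                  config.percentile_convention)
        except Exception as exc:
            log.error("case %s failed: %s", case_id, exc)
            failures.append({"case_id": case_id, "error": str(exc)})
            continue
        rec = dict(row)
        rec.pop("volume_path", None)
        rec.pop("mask_path", None)
        rec.update(dens.as_dict())
        case_rows.append(rec)

    cases_df = pd.DataFrame(case_rows)
    if cases_df.empty:
        raise LungDensError("no case could be processed")
    records = dataframe_to_records(cases_df)
    included, exclusions = apply_inclusion_criteria(records)
    if not included:
        raise LungDensError("included cohort is empty after exclusion filtering")

    table = render_summary_table(included, config.alpha, config.t_variant,
                                 config.stats_mode)

    outputs = {
        "cases": out / "cases.csv",
        "comparisons_csv": out / "comparisons.csv",
        "comparisons_json": out / "comparisons.json",
        "exclusions": out / "exclusions.csv",
        "run_log": out / "run_log.json",
    }
    cases_df.to_csv(outputs["cases"], index=False)
    table.to_csv(outputs["comparisons_csv"], index=False)
    with open(outputs["comparisons_json"], "w") as fh:
        json.dump(json.loads(table.to_json(orient="records")), fh, indent=2,
                  sort_keys=True)
    pd.DataFrame(exclusions, columns=["case_id", "reason"]).to_csv(
        outputs["exclusions"], index=False)
    with open(outputs["run_log"], "w") as fh:
        json.dump({
            "software_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "segmentation_provenance": provenance,
            "failures": failures,
            "n_processed": len(case_rows),
            "n_included": len(included),
        }, fh, indent=2, sort_keys=True)

    return RunReport(
        n_processed=len(case_rows), n_failed=len(failures),
        n_included=len(included),
        outputs={k: str(v) for k, v in outputs.items()},
        exit_code=2 if failures else 0)
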