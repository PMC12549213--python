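"""Manifest-driven batch orchestration.

Runs the full per-field pipeline (detect specks -> segment cells ->
assign -> count) for every field in a manifest, pools counts per sample,
computes %ASC, and classifies against condition-matched reference
ranges. A sample with a missing or unreadable image fails with a logged
reason; the rest of the batch continues.

Manual correction of misidentified objects is supported as an override
CSV (field_id, corrected_cells, corrected_specks) applied before
pooling, replacing the interactive click-to-correct workflow.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .detection import DetectionParams, detect_specks
from .io import ChannelConfig, load_field, normalize_channel, read_manifest
from .quantify import (
    FieldCounts,
    ReferenceRange,
    SampleResult,
    assign_specks,
    summarise_sample,
)
from .segmentation import SegmentationParams, segment_cells

logger = logging.getLogger("speckquant")

RESULT_COLUMNS = [
    "sample_id",
    "condition",
    "n_fields",
    "pooled_cells",
    "pooled_specks",
    "pct_asc",
    "classification",
    "status",
    "config_hash",
]
AUDIT_COLUMNS = [
    "sample_id",
    "condition",
    "field_id",
    "n_cells",
    "n_specks_intracellular",
    "n_specks_total",
    "overridden",
]


@dataclass
class RunConfig:
    detection: DetectionParams = dc_field(default_factory=DetectionParams)
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    rr_table: Dict[str, ReferenceRange] = dc_field(default_factory=dict)
    pixel_size_um: float = 0.5

    def hash(self) -> str:
        """Short provenance hash over every tunable."""
        payload = json.dumps(
            {
                "detection": self.detection.__dict__,
                "segmentation": self.segmentation.__dict__,
                "rr": {k: v.__dict__ for k, v in sorted(self.rr_table.items())},
                "pixel_size_um": self.pixel_size_um,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read a TOML config with optional [detection] and [segmentation] tables."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return RunConfig(
        detection=DetectionParams(**raw.get("detection", {})),
        segmentation=SegmentationParams(**raw.get("segmentation", {})),
        pixel_size_um=raw.get("pixel_size_um", 0.5),
    )


def read_rr_table(path) -> Dict[str, ReferenceRange]:
    """Read reference ranges from CSV (condition, n, mean, ci_low, ci_high)."""
    df = pd.read_csv(path)
    table: Dict[str, ReferenceRange] = {}
    for _, row in df.iterrows():
        cond = str(row["condition"])
        if cond in table:
            raise ValueError(f"duplicate reference range for condition {cond!r}")
        table[cond] = ReferenceRange(
            condition=cond,
            n=int(row["n"]),
            mean=float(row["mean"]),
            ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]),
        )
    return table


def read_overrides(path) -> Dict[str, Tuple[Optional[int], Optional[int]]]:
    """Manual-correction CSV: field_id, corrected_cells, corrected_specks."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        cells = None if pd.isna(row.get("corrected_cells")) else int(row["corrected_cells"])
        specks = None if pd.isna(row.get("corrected_specks")) else int(row["corrected_specks"])
        out[str(row["field_id"])] = (cells, specks)
    return out


def process_field(
    field_row: dict, config: RunConfig
) -> FieldCounts:
    """Detect, segment and count one field from its manifest row."""
    field = load_field(
        ChannelConfig(field_row["nuclear_path"], field_row["asc_path"]),
        field_id=str(field_row["field_id"]),
        pixel_size_um=config.pixel_size_um,
    )
    specks = detect_specks(field, config.detection)
    labelmap = segment_cells(
        normalize_channel(field.nuclear, field.bit_depth), config.segmentation
    )
    _, counts = assign_specks(specks, labelmap, field_id=field.field_id)
    return counts


def _apply_override(
    counts: FieldCounts, override: Tuple[Optional[int], Optional[int]]
) -> FieldCounts:
    cells, specks = override
    return FieldCounts(
        field_id=counts.field_id,
        n_cells=counts.n_cells if cells is None else cells,
        n_specks_intracellular=(
            counts.n_specks_intracellular if specks is None else specks
        ),
        n_specks_total=max(
            counts.n_specks_total,
            counts.n_specks_intracellular if specks is None else specks,
        ),
    )


def run_sample(
    sample_rows: pd.DataFrame,
    config: RunConfig,
    overrides: Optional[Dict[str, Tuple[Optional[int], Optional[int]]]] = None,
) -> Tuple[SampleResult, List[FieldCounts], List[bool]]:
    """Process all replicate fields of one sample and pool them."""
    conditions = set(sample_rows["condition"])
    if len(conditions) != 1:
        raise ValueError(
            f"sample {sample_rows['sample_id'].iloc[0]!r} mixes conditions {sorted(conditions)}"
        )
    condition = conditions.pop()
    overrides = overrides or {}
    per_field: List[FieldCounts] = []
    overridden: List[bool] = []
    for _, row in sample_rows.iterrows():
        counts = process_field(row.to_dict(), config)
        hit = str(row["field_id"]) in overrides
        if hit:
            counts = _apply_override(counts, overrides[str(row["field_id"])])
        per_field.append(counts)
        overridden.append(hit)
    rr = config.rr_table.get(condition)
    result = summarise_sample(
        str(sample_rows["sample_id"].iloc[0]), condition, per_field, rr
    )
    return result, per_field, overridden


def run_batch(
    manifest: pd.DataFrame,
    config: RunConfig,
    overrides: Optional[Dict[str, Tuple[Optional[int], Optional[int]]]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, int]:
    """Run every sample in a manifest.

    Returns (results table, per-field audit table, n_failed). Row order
    is deterministic (sample_id ascending); a failed sample keeps a row
    with status 'failed' and NaN quantities.
    """
    cfg_hash = config.hash()
    results = []
    audit = []
    n_failed = 0
    for sample_id in sorted(manifest["sample_id"].unique()):
        rows = manifest[manifest["sample_id"] == sample_id]
        try:
            result, per_field, overridden = run_sample(rows, config, overrides)
        except Exception as exc:  # noqa: BLE001 - batch must survive bad samples
            logger.error("sample %s failed: %s", sample_id, exc)
            n_failed += 1
            results.append(
                {
                    "sample_id": sample_id,
                    "condition": rows["condition"].iloc[0],
                    "n_fields": len(rows),
                    "pooled_cells": None,
                    "pooled_specks": None,
                    "pct_asc": None,
                    "classification": "failed",
                    "status": f"failed: {exc}",
                    "config_hash": cfg_hash,
                }
            )
            continue
        logger.info(
            "sample %s: %d cells, %d specks, %%ASC=%.2f (%s)",
            sample_id,
            result.pooled_cells,
            result.pooled_specks,
            result.pct_asc,
            result.classification,
        )
        results.append(
            {
                "sample_id": result.sample_id,
                "condition": result.condition,
                "n_fields": len(per_field),
                "pooled_cells": result.pooled_cells,
                "pooled_specks": result.pooled_specks,
                "pct_asc": result.pct_asc,
                "classification": result.classification,
                "status": "ok",
                "config_hash": cfg_hash,
            }
        )
        for counts, hit in zip(per_field, overridden):
            audit.append(
                {
                    "sample_id": result.sample_id,
                    "condition": result.condition,
                    "field_id": counts.field_id,
                    "n_cells": counts.n_cells,
                    "n_specks_intracellular": counts.n_specks_intracellular,
                    "n_specks_total": counts.n_specks_total,
                    "overridden": hit,
                }
            )
    return (
        pd.DataFrame(results, columns=RESULT_COLUMNS),
        pd.DataFrame(audit, columns=AUDIT_COLUMNS),
        n_failed,
    )


def run_batch_files(
    manifest_path,
    out_dir,
    config: Optional[RunConfig] = None,
    overrides_path=None,
) -> int:
    """File-level entry point: manifest in, results.csv + audit.csv out.

    Returns the number of failed samples (the CLI exit code).
    """
    manifest = read_manifest(manifest_path)
    config = config or RunConfig()
    overrides = read_overrides(overrides_path) if overrides_path else None
    results, audit, n_failed = run_batch(manifest, config, overrides)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results.to_csv(out_dir / "results.csv", index=False)
    audit.to_csv(out_dir / "audit.csv", index=False)
    return n_failed
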