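"""Config-driven batch runner: folder-per-stage, log-per-stage processing.

A dataset is a root directory holding one field of view per subfolder
(folder dialect) or per multipage TIFF.  The configured stages — by default
crosstalk removal, then denoising, then aggregate removal — are applied in
order to every FOV; each stage reads the previous stage's output, writes a
new folder named with its suffix, and drops a JSON parameter log beside the
images.  Total counts can only decrease: every stage removes counts, never
creates them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregates import AggregateParams, remove_aggregates_stack
from .crosstalk import CrosstalkParams, remove_crosstalk_rules
from .denoise import DenoiseParams, denoise_stack
from .image_io import STAGE_SUFFIXES, read_stack, write_log, write_stack
from .stack import ChannelStack, MbicleanError

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "FAILURE_MARKER"]

#: Dropped in output_root when a run aborts, flagging partial outputs.
FAILURE_MARKER = "RUN_FAILED.txt"

_TIFF_EXTS = (".tif", ".tiff")


@dataclasses.dataclass
class PipelineConfig:
    """Batch run description.

    ``stages`` is an ordered list of dicts, each with a ``stage`` key
    (crosstalk | denoise | aggregates) and its parameter table:
    crosstalk takes ``rules`` (list of CrosstalkParams fields), the other
    two take ``channels`` (lists of DenoiseParams / AggregateParams fields).
    """

    input_root: str
    output_root: str
    stages: Sequence[dict] = ()
    overwrite: bool = False
    dialect: str = "auto"

    def __post_init__(self) -> None:
        self.stages = [dict(s) for s in self.stages]
        for s in self.stages:
            if s.get("stage") not in STAGE_SUFFIXES:
                raise ValueError(
                    f"each stage needs 'stage' in {sorted(STAGE_SUFFIXES)}, got {s.get('stage')!r}"
                )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML (or JSON, a YAML subset)."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return PipelineConfig(**payload)


def _discover_fovs(root: Path) -> list[Path]:
    fovs = sorted(p for p in root.iterdir() if p.is_dir())
    fovs += sorted(p for p in root.iterdir() if p.is_file() and p.suffix.lower() in _TIFF_EXTS)
    if not fovs:
        raise MbicleanError(f"no fields of view (subfolders or TIFFs) found in {root}")
    return fovs


def _apply_stage(stack: ChannelStack, stage_cfg: dict):
    stage = stage_cfg["stage"]
    if stage == "crosstalk":
        rules = [CrosstalkParams(**r) for r in stage_cfg.get("rules", [])]
        return remove_crosstalk_rules(stack, rules)
    if stage == "denoise":
        params = [DenoiseParams(**p) for p in stage_cfg.get("channels", [])]
        return denoise_stack(stack, params)
    if stage == "aggregates":
        params = [AggregateParams(**p) for p in stage_cfg.get("channels", [])]
        return remove_aggregates_stack(stack, params)
    raise ValueError(f"unknown stage {stage!r}")


def _summary_rows(fov: str, stage: str, before: ChannelStack, after: ChannelStack) -> list[dict]:
    rows = []
    for b, a in zip(before, after):
        rows.append(
            {
                "fov": fov,
                "stage": stage,
                "channel": b.name,
                "counts_before": float(b.counts.sum()),
                "counts_after": float(a.counts.sum()),
                "pixels_altered": int(np.count_nonzero(b.counts != a.counts)),
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run all configured stages over every FOV under ``input_root``.

    Returns a summary DataFrame (per FOV, stage and channel: total counts
    before/after and pixels altered).  On any stage error a failure marker
    file is written to ``output_root`` and the error is re-raised, flagging
    partial outputs.
    """
    input_root = Path(config.input_root)
    output_root = Path(config.output_root)
    output_root.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    try:
        for fov_path in _discover_fovs(input_root):
            dialect = "folder" if fov_path.is_dir() else "multipage"
            stack = read_stack(fov_path, dialect)
            current_name = fov_path.name if fov_path.is_dir() else fov_path.stem
            if not config.stages:
                # zero stages: mirror the input so downstream tooling still
                # finds one folder per FOV under output_root
                out_dir = output_root / current_name
                write_stack(stack, out_dir, dialect="folder", overwrite=config.overwrite)
                rows.extend(_summary_rows(stack.fov_id, "mirror", stack, stack))
                continue
            in_path = fov_path
            for stage_cfg in config.stages:
                cleaned, log = _apply_stage(stack, stage_cfg)
                current_name = current_name + STAGE_SUFFIXES[stage_cfg["stage"]]
                out_dir = output_root / current_name
                write_stack(cleaned, out_dir, dialect="folder", overwrite=config.overwrite)
                log.input_path = str(in_path)
                log.output_path = str(out_dir)
                log.parameters["config_hash"] = config.config_hash()
                log.software_version = __version__
                write_log(log, out_dir)
                rows.extend(_summary_rows(stack.fov_id, stage_cfg["stage"], stack, cleaned))
                stack, in_path = cleaned, out_dir
    except Exception as exc:
        marker = output_root / FAILURE_MARKER
        marker.write_text(f"pipeline run failed: {exc}\n", encoding="utf-8")
        raise
    return pd.DataFrame(
        rows,
        columns=["fov", "stage", "channel", "counts_before", "counts_after", "pixels_altered"],
    )

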