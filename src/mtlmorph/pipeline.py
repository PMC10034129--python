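"""Config-driven orchestration, evaluation metrics, and run reporting."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml
from scipy import ndimage as ndi

log = logging.getLogger("mtlmorph")


# ---------------------------------------------------------------------------
# evaluation metrics


def dice_score(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice = 2|A ^ B| / (|A| + |B|); both-empty defined as 1."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return float(2.0 * np.sum(a & b) / (sa + sb))


def hd95(mask_a: np.ndarray, mask_b: np.ndarray, spacing=None) -> float:
    """95th-percentile symmetric boundary distance (mm when spacing given).

    Both-empty is defined as 0; one-empty is undefined and raises.
    """
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    if not a.any() and not b.any():
        return 0.0
    if not a.any() or not b.any():
        raise ValueError("one mask is empty; HD95 undefined")
    spacing = np.ones(a.ndim) if spacing is None else np.asarray(spacing, float)

    def boundary(m):
        er = ndi.binary_erosion(m)
        return m & ~er

    ba, bb = boundary(a), boundary(b)
    dt_a = ndi.distance_transform_edt(~ba, sampling=spacing)
    dt_b = ndi.distance_transform_edt(~bb, sampling=spacing)
    d_ab = dt_b[ba]
    d_ba = dt_a[bb]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def overlap_metrics(mask_a: np.ndarray, mask_b: np.ndarray, spacing=None) -> dict:
    return {"dice": dice_score(mask_a, mask_b),
            "hd95": hd95(mask_a, mask_b, spacing)}


# ---------------------------------------------------------------------------
# configuration and run reporting


STOCHASTIC_STAGES = {"simulate-cohort", "simulate-histology", "group-test",
                     "register-stack"}


@dataclass
class PipelineConfig:
    stages: List[dict]
    output_dir: str = "mtlmorph_output"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(stages=raw.get("stages", []),
                  output_dir=raw.get("output_dir", "mtlmorph_output"),
                  log_level=raw.get("log_level", "INFO"))
        cfg.validate()
        return cfg

    def validate(self):
        for st in self.stages:
            if "name" not in st:
                raise ValueError("every stage needs a name")
            if st["name"] in STOCHASTIC_STAGES and "seed" not in st.get("params", {}):
                raise ValueError(
                    f"stochastic stage '{st['name']}' requires an explicit seed")
            for key in ("input", "inputs"):
                if key in st:
                    paths = st[key] if isinstance(st[key], list) else [st[key]]
                    for p in paths:
                        if not Path(p).exists():
                            raise FileNotFoundError(f"stage {st['name']}: {p}")


@dataclass
class RunReport:
    stages: List[dict] = field(default_factory=list)
    manifest: Dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, seconds: float, params: dict,
                  outputs: List[Path], extra: Optional[dict] = None):
        self.stages.append({"name": name, "seconds": seconds, "params": params,
                            **(extra or {})})
        for p in outputs:
            p = Path(p)
            self.manifest[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path):
        Path(path).write_text(json.dumps(
            {"stages": self.stages, "manifest": self.manifest}, indent=2,
            default=str))


def run(config: PipelineConfig) -> RunReport:
    """Execute configured stages in order; see cli for the stage registry."""
    from . import cli as _cli
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    for st in config.stages:
        name = st["name"]
        params = dict(st.get("params", {}))
        log.info("stage %s: params=%s", name, params)
        fn = _cli.STAGES.get(name)
        if fn is None:
            raise ValueError(f"unknown stage '{name}'")
        t0 = time.time()
        outputs, extra = fn(out_dir, **params)
        report.add_stage(name, time.time() - t0, params, outputs, extra)
    report.write(out_dir / "run_report.json")
    return report
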