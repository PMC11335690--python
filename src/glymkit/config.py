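"""Run configuration and the reproducibility manifest.

Every pipeline stage appends its parameters and input checksums to a run
manifest so that any stage can be re-executed from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["RunManifest", "RunConfig", "checksum"]


def checksum(obj: Any) -> str:
    """Short deterministic digest of an array / mapping / scalar."""
    h = hashlib.sha256()
    if isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
        h.update(str(obj.shape).encode())
    else:
        h.update(json.dumps(obj, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Ordered record of pipeline stages, their parameters and input digests."""

    stages: list[dict] = field(default_factory=list)
    include_timestamps: bool = False  # off by default: manifests stay byte-reproducible

    def log_stage(self, name: str, params: dict, inputs: dict[str, Any] | None = None) -> None:
        entry: dict[str, Any] = {
            "stage": name,
            "params": _jsonable(params),
            "inputs": {k: checksum(v) for k, v in (inputs or {}).items()},
        }
        if self.include_timestamps:
            entry["time"] = time.time()
        self.stages.append(entry)

    def save(self, path: str | os.PathLike) -> str:
        with open(str(path), "w") as fh:
            json.dump({"manifest": self.stages}, fh, indent=2, sort_keys=True)
        return str(path)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dict__") and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    return obj


@dataclass
class RunConfig:
    """End-to-end run settings for the demo pipeline.

    A seed is mandatory whenever any stochastic stage is enabled; all sizes
    are deliberately small so a full demo completes in well under a minute
    on one CPU.
    """

    seed: int = 0
    out_dir: str = "glymkit_demo"
    # cohort stage
    n_control: int = 37
    n_mtbi: int = 44
    # imaging stage: number of subjects for which phantom images are
    # synthesized and pushed through the ePVS + ALPS pipelines
    n_imaging_subjects: int = 3
    structural_shape: tuple[int, int, int] = (40, 40, 40)
    structural_spacing: float = 1.0
    dwi_snr: float = 30.0
    run_imaging: bool = True
    run_stats: bool = True

    def to_json(self) -> str:
        return json.dumps(_jsonable(vars(self)), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        with open(str(path)) as fh:
            raw = json.load(fh)
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            if k == "structural_shape":
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg
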