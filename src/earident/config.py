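"""Run configuration: defaults, key=value serialization, config hashing.

Every experiment is fully described by a :class:`RunConfig`; outputs embed
its short hash so a run can be reproduced byte-for-byte from the config
alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

from .cohort import CaptureModel, default_donut_model, default_freehand_model
from .features import SiftParams


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one end-to-end experiment."""

    # cohort
    n_subjects: int = 50
    cohort_seed: int = 0
    donut_model: CaptureModel = field(default_factory=default_donut_model)
    freehand_model: CaptureModel = field(default_factory=default_freehand_model)
    # preprocess
    target_long_side: int = 256
    freehand_crop_length: int = 340
    freehand_crop_width: int = 260
    # features
    sift: SiftParams = field(default_factory=SiftParams)
    backend: str = "native"
    # matching
    ratio_threshold: float = 0.75
    # evaluation / sensitivity
    sweep_values: Tuple[int, ...] = (140, 200, 260, 320)
    sweep_fixed_length: int = 340
    sweep_fixed_width: int = 240
    # output
    out_dir: str = "earident_run"

    def serialize(self) -> str:
        """Flat ``key=value`` text, one per line, deterministic order."""
        flat = {}

        def walk(prefix: str, obj) -> None:
            if hasattr(obj, "__dataclass_fields__"):
                for f in fields(obj):
                    walk(f"{prefix}{f.name}.", getattr(obj, f.name))
            elif isinstance(obj, (tuple, list)):
                flat[prefix[:-1]] = ",".join(str(v) for v in obj)
            else:
                flat[prefix[:-1]] = str(obj)

        walk("", self)
        return "\n".join(f"{k}={v}" for k, v in sorted(flat.items())) + "\n"

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.serialize().encode()).hexdigest()[:12]

    def write(self, path: Path | str) -> None:
        Path(path).write_text(self.serialize())
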