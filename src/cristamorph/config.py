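"""Pipeline configuration: one YAML document with per-stage blocks.

Interactive choices in the original workflow (threshold picking, ROI
highlighting) are irreproducible; here every stage parameter lives in a
config that round-trips losslessly to YAML and is echoed into the run
report, so any number in the output can be traced to parameters + seed.
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]

_SEG_DEFAULTS = dict(method="otsu", threshold=None, min_size=150,
                     close_iters=1, min_ics_voxels=60, z_trim=3)
_MORPH_DEFAULTS = dict(contact_tol_nm=10.0, with_fenestrations=False,
                       membrane_thickness_nm=6.0)


@dataclass
class PipelineConfig:
    """Per-stage parameter blocks; dict blocks hold the keyword arguments
    of the corresponding stage constructors."""

    phantom: dict | None = None         # PhantomSpec kwargs, or None
    filters: dict = field(default_factory=dict)       # FilterParams kwargs
    segmentation: dict = field(default_factory=dict)
    morphometry: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)      # ClassifyConfig kwargs
    input_volume: str | None = None     # MRC path when not simulating
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        seg = dict(_SEG_DEFAULTS)
        unknown = set(self.segmentation) - set(seg)
        if unknown:
            raise ValueError(f"unknown segmentation keys: {sorted(unknown)}")
        seg.update(self.segmentation)
        self.segmentation = seg
        mor = dict(_MORPH_DEFAULTS)
        unknown = set(self.morphometry) - set(mor)
        if unknown:
            raise ValueError(f"unknown morphometry keys: {sorted(unknown)}")
        mor.update(self.morphometry)
        self.morphometry = mor
        if self.phantom is None and self.input_volume is None:
            raise ValueError("config needs either a phantom block or an "
                             "input_volume path")

    # ---- round trip -------------------------------------------------------
    def to_dict(self) -> dict:
        def norm(x):
            if isinstance(x, dict):
                return {k: norm(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [norm(v) for v in x]
            return x
        # tuples serialise as YAML lists; normalise so a round trip is exact
        return norm(asdict(self))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
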