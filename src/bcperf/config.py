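"""Run configuration: validated defaults, YAML round trip, flag overrides."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "DEFAULT_EPOCH_DEFS"]

# Epoch windows in seconds, half-open [start, end), anchored at stimulus
# onset (active epochs) or offset (post-stimulus epochs).  At TR 2.5 s and
# four cycles each window contributes 4 samples per cycle, 16 in total.
DEFAULT_EPOCH_DEFS: dict[str, tuple[str, float, float]] = {
    "transient_on": ("onset", 0.0, 10.0),
    "steady_state": ("onset", 10.0, 20.0),
    "transient_off": ("offset", 0.0, 10.0),
    "undershoot": ("offset", 12.5, 22.5),
}


@dataclass
class RunConfig:
    """All knobs of the simulate -> preprocess -> fit -> calibrate pipeline.

    Every field has a validated default; unknown keys in a config file are
    rejected.  Identical config plus seed reproduces byte-identical numeric
    outputs.
    """

    out_dir: str = "bcp_out"
    seed: int = 0
    # acquisition / design
    tr: float = 2.5
    parity: str = "tag-first"
    pre_rest_s: float = 60.0
    n_cycles: int = 4
    on_s: float = 20.0
    off_s: float = 60.0
    post_rest_s: float = 30.0
    # physiology
    alpha_v: float = 0.2
    m_scale: float = 0.11
    lam: float = 0.35
    amp_task: float = 0.46
    amp_hypercapnia: float = 0.5
    f0: float = 28.0
    b0: float = 11200.0
    # noise
    sigma_asl_frac: float = 0.36
    sigma_bold_frac: float = 0.005
    drift_per_frame: float = 0.0
    n_roi_voxels: int = 50
    n_csf_voxels: int = 20
    # baselines
    baseline_n_task: int = 20
    baseline_n_calibration: int = 40
    # search
    bracket_lo: float = -0.1
    bracket_hi: float = 0.3
    tolerance: float = 1e-3
    f_floor: float = 0.05
    f_cap: float = 5.0
    # epoch windows: name -> (anchor, start_s, end_s)
    epochs: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EPOCH_DEFS)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.parity not in ("tag-first", "control-first"):
            raise ValueError("parity must be 'tag-first' or 'control-first'")
        if not self.bracket_lo < self.bracket_hi:
            raise ValueError("degenerate k bracket: bracket_lo must be < bracket_hi")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.m_scale <= 0:
            raise ValueError("m_scale must be positive")
        if self.f0 <= 0 or self.b0 <= 0:
            raise ValueError("baselines f0/b0 must be positive")
        if self.sigma_asl_frac < 0 or self.sigma_bold_frac < 0:
            raise ValueError("noise fractions must be non-negative")
        if self.n_roi_voxels < 1 or self.n_csf_voxels < 1:
            raise ValueError("voxel counts must be at least 1")
        if self.baseline_n_task < 1 or self.baseline_n_calibration < 1:
            raise ValueError("baseline sample counts must be at least 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name, (anchor, start, end) in self.epochs.items():
            if anchor not in ("onset", "offset"):
                raise ValueError(f"epoch {name!r}: anchor must be onset/offset")
            if not end > start:
                raise ValueError(f"epoch {name!r}: end must exceed start")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "epochs" in d:
            d["epochs"] = {
                name: (str(spec[0]), float(spec[1]), float(spec[2]))
                for name, spec in d["epochs"].items()
            }
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["epochs"] = {name: list(spec) for name, spec in self.epochs.items()}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
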