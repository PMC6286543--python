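"""Run configuration and provenance.

Every analysis parameter defaults to the protocol value where one exists:
3-fold eGFP threshold, 100-um cluster merge, 8-um rings to ~300 um
(37 full rings = 296 um), 100-um BAT window, 50-um autoradiography bins
to 300 um, 10-min tracer / 8-h drug circulation endpoints.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "provenance"]


@dataclass
class RunConfig:
    """Pipeline parameters with protocol defaults, YAML round-trippable."""

    # segmentation
    fold_threshold: float = 3.0  # eGFP fold over background
    max_gap_um: float = 100.0  # cluster-merge rule
    # ring analysis
    ring_width_um: float = 8.0
    ring_extent_um: float = 296.0  # 37 full rings per direction
    bat_window_um: tuple[float, float] = (0.0, 100.0)
    # kinetics
    tracer_circulation_s: float = 600.0  # 10 min
    drug_circulation_s: float = 28800.0  # 8 h
    au_to_amount_per_g: float = 1.0  # optional fluorescence calibration, pass-through
    # autoradiography
    calibration_form: str = "linear"
    autorad_bin_width_um: float = 50.0
    autorad_extent_um: float = 300.0
    # general
    pixel_size_um: float | None = None  # override TIFF metadata when set
    seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bat_window_um" in data:
            data["bat_window_um"] = tuple(data["bat_window_um"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["bat_window_um"] = list(data["bat_window_um"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def provenance(config: RunConfig, seed: int | None = None) -> dict:
    """Deterministic provenance record written next to every CLI output."""
    import numpy
    import scipy

    from . import __version__

    return {
        "batperm_version": __version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "config": asdict(config),
        "config_sha256_16": config.digest(),
        "seed": config.seed if seed is None else seed,
    }
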