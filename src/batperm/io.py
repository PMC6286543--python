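"""Readers and writers: TIFF sections, CSV tables, YAML configs.

Sections travel as multi-page TIFF (one page per channel) with pixel size
and channel names stored as a JSON image description, so a round trip
preserves physical scale without sidecar files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import BloodCurve, SectionImage, TissueUptake

__all__ = [
    "write_section",
    "read_section",
    "write_labels",
    "read_labels",
    "read_blood_curve_csv",
    "write_blood_curve_csv",
    "read_tissue_uptake_csv",
    "read_standards_csv",
]


def write_section(path: str | Path, section: SectionImage) -> None:
    """Write a section as multi-page float32 TIFF with JSON metadata."""
    names = list(section.channels)
    stack = np.stack([section.channels[n] for n in names]).astype(np.float32)
    desc = json.dumps(
        {"pixel_size_um": section.pixel_size, "channels": names, "id": section.id}
    )
    tifffile.imwrite(str(path), stack, description=desc)


def read_section(path: str | Path, pixel_size: float | None = None) -> SectionImage:
    """Read a multi-page TIFF section; ``pixel_size`` overrides metadata."""
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if stack.ndim == 2:
        stack = stack[None]
    names = meta.get("channels") or [f"channel{i}" for i in range(stack.shape[0])]
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(
            f"{path}: no pixel size in TIFF metadata and none supplied"
        )
    return SectionImage(
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        pixel_size=float(px),
        id=str(meta.get("id", Path(path).stem)),
    )


def write_labels(path: str | Path, labels: np.ndarray, pixel_size: float) -> None:
    desc = json.dumps({"pixel_size_um": pixel_size, "kind": "labels"})
    tifffile.imwrite(str(path), labels.astype(np.int32), description=desc)


def read_labels(path: str | Path) -> tuple[np.ndarray, float | None]:
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray().astype(np.int32)
        desc = tif.pages[0].description
    px = None
    if desc:
        try:
            px = json.loads(desc).get("pixel_size_um")
        except (json.JSONDecodeError, TypeError):
            px = None
    return arr, px


def write_blood_curve_csv(path: str | Path, curve: BloodCurve) -> None:
    pd.DataFrame({"time_s": curve.times, "conc": curve.concentrations}).to_csv(
        path, index=False
    )


def read_blood_curve_csv(path: str | Path, tracer_id: str = "") -> BloodCurve:
    """Read a blood curve CSV with ``time_s`` and ``conc`` columns."""
    df = pd.read_csv(path)
    missing = {"time_s", "conc"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return BloodCurve(
        times=df["time_s"].to_numpy(dtype=float),
        concentrations=df["conc"].to_numpy(dtype=float),
        tracer_id=tracer_id,
    )


def read_tissue_uptake_csv(path: str | Path) -> list[TissueUptake]:
    """Read per-subject terminal uptakes: subject, region, C_br, T_s."""
    df = pd.read_csv(path)
    missing = {"subject", "region", "C_br", "T_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TissueUptake(
            region=str(r.region).lower(),
            c_br=float(r.C_br),
            t_end=float(r.T_s),
            subject_id=str(r.subject),
        )
        for r in df.itertuples()
    ]


def read_standards_csv(path: str | Path) -> pd.DataFrame:
    """Read calibration standards: concentration_ng_per_g, intensity."""
    df = pd.read_csv(path)
    missing = {"concentration_ng_per_g", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
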