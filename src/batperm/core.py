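"""Shared data containers for the permeability-profiling pipeline.

All rasters are 2-D numpy arrays indexed ``[row, col]`` with 0-based
indices; physical coordinates are pixel-center coordinates, i.e. pixel
``(i, j)`` sits at ``(i * pixel_size, j * pixel_size)`` micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SectionImage",
    "BinaryMask",
    "LesionSet",
    "RadialProfile",
    "BloodCurve",
    "TissueUptake",
]


@dataclass
class SectionImage:
    """A registered multi-channel 2-D section with physical pixel size.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"egfp"``, ``"tracer"``) to a 2-D
        float raster in arbitrary fluorescence/densitometry units (AU).
    pixel_size
        Physical edge length of one pixel, in micrometres.
    id
        Free-text identifier carried through to output tables.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels must share one shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class BinaryMask:
    """Boolean per-pixel region of interest tied to a pixel size."""

    raster: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def area_um2(self) -> float:
        return float(self.raster.sum()) * self.pixel_size**2


@dataclass
class LesionSet:
    """Labelled lesions produced by cluster merging.

    ``labels`` carries the lesion id on the *original* tumor-mask pixels
    (0 = background).  ``hulls`` carries the same ids on the closed lesion
    footprint (gaps between merged clusters and interior holes filled);
    margins and signed distances are defined on the hull.
    """

    labels: np.ndarray
    hulls: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.hulls = np.asarray(self.hulls)
        if self.labels.shape != self.hulls.shape:
            raise ValueError("labels and hulls must share one shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def lesion_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_lesions(self) -> int:
        return int(self.lesion_ids.size)

    def area_um2(self, k: int) -> float:
        """Area of lesion ``k`` counted over original mask pixels."""
        self._check(k)
        return float((self.labels == k).sum()) * self.pixel_size**2

    def hull_mask(self, k: int) -> np.ndarray:
        self._check(k)
        return self.hulls == k

    def _check(self, k: int) -> None:
        if k not in self.lesion_ids:
            raise KeyError(f"no lesion with label {k}")

    def table(self) -> pd.DataFrame:
        """Per-lesion summary (id, area in um^2, centroid in um)."""
        rows = []
        for k in self.lesion_ids:
            rr, cc = np.nonzero(self.labels == k)
            rows.append(
                {
                    "lesion_id": int(k),
                    "area_um2": self.area_um2(int(k)),
                    "centroid_row_um": float(rr.mean()) * self.pixel_size,
                    "centroid_col_um": float(cc.mean()) * self.pixel_size,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class RadialProfile:
    """Per-ring values versus signed distance from the lesion margin.

    Negative distances are inside the tumor hull, positive distances are
    in the surrounding brain.  ``value`` holds either sum-intensity per
    unit area (AU/um^2, fluorescence) or a mean concentration (ng/g,
    autoradiography); ``units`` says which.  When ``reference`` is set,
    ``fold`` is ``value / reference`` bin-wise.
    """

    bin_lo: np.ndarray
    bin_hi: np.ndarray
    n_pixels: np.ndarray
    value: np.ndarray
    units: str
    reference: float | None = None
    lesion_id: int | None = None

    def __post_init__(self) -> None:
        self.bin_lo = np.asarray(self.bin_lo, dtype=float)
        self.bin_hi = np.asarray(self.bin_hi, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        n = self.bin_lo.size
        if not (self.bin_hi.size == self.n_pixels.size == self.value.size == n):
            raise ValueError("profile columns must have equal length")

    @property
    def fold(self) -> np.ndarray:
        if self.reference is None:
            raise ValueError("profile has no reference; fold undefined")
        if self.reference <= 0:
            raise ValueError("reference must be > 0")
        return self.value / self.reference

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_lo + self.bin_hi)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin_lo_um": self.bin_lo,
                "bin_hi_um": self.bin_hi,
                "n_pixels": self.n_pixels,
                f"value_{self.units}": self.value,
            }
        )
        if self.reference is not None:
            df["fold"] = self.fold
        if self.lesion_id is not None:
            df.insert(0, "lesion_id", self.lesion_id)
        return df


@dataclass
class BloodCurve:
    """Tracer concentration in blood over time after a bolus dose."""

    times: np.ndarray  # seconds, strictly increasing, starting at 0
    concentrations: np.ndarray  # amount per mL of blood
    tracer_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.size != self.concentrations.size:
            raise ValueError("times and concentrations must align")
        if self.times.size < 2:
            raise ValueError("need at least 2 samples")
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and strictly increase")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass
class TissueUptake:
    """Terminal tissue amount for one subject and region.

    ``c_br`` is the amount of compound per gram of tissue at time ``t_end``
    (seconds after bolus), in units consistent with the blood curve's
    amount-per-mL.
    """

    region: str  # "normal" | "bat" | "tumor"
    c_br: float
    t_end: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.c_br < 0:
            raise ValueError("c_br must be >= 0")
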