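"""Circumferential ring-ROI analysis around lesion margins.

A signed Euclidean distance map (negative inside the lesion hull) drives
consecutive annular ROIs of fixed radial width (8 um by default) out to
+/- 296 um from the margin — 37 full rings per direction, the closest
whole-ring coverage of the nominal 300 um extent.  Per-ring sum intensity
per unit area, normalised to a contralateral normal-brain reference,
gives the fold-change permeability profile; the mean fold over the first
100 um outside the margin summarises the brain-adjacent-to-tumor (BAT)
window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import BinaryMask, LesionSet, RadialProfile, SectionImage
from .segmentation import margin_mask

__all__ = [
    "RingSet",
    "signed_distance_map",
    "signed_distance_map_bruteforce",
    "build_rings",
    "territory_exclusions",
    "contralateral_reference",
    "ring_statistics",
    "bat_mean_fold",
]

logger = logging.getLogger(__name__)


def signed_distance_map(lesions: LesionSet, k: int) -> np.ndarray:
    """Signed Euclidean distance (um) to the nearest margin pixel of lesion k.

    Positive outside the lesion hull, negative inside; margin pixels are 0.
    """
    m = margin_mask(lesions, k)
    d = ndi.distance_transform_edt(~m) * lesions.pixel_size
    sign = np.where(lesions.hull_mask(k), -1.0, 1.0)
    return d * sign


def signed_distance_map_bruteforce(lesions: LesionSet, k: int) -> np.ndarray:
    """Exhaustive per-pixel minimum over margin pixels (test oracle)."""
    m = margin_mask(lesions, k)
    coords = np.argwhere(m).astype(float)
    h, w = m.shape
    rr, cc = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d = np.sqrt(((pts[:, None, :] - coords[None, :, :]) ** 2).sum(-1)).min(1)
    d = d.reshape(h, w) * lesions.pixel_size
    return d * np.where(lesions.hull_mask(k), -1.0, 1.0)


@dataclass
class RingSet:
    """Ordered disjoint annular masks indexed by signed-distance bins.

    ``bin_index`` assigns each pixel the index of its bin in ``bins`` (or
    -1 when outside every ring or excluded).  Bins are half-open ``(lo,
    hi]`` on the signed distance, so margin pixels (d = 0) fall in the
    first inward bin.
    """

    lesion_id: int
    ring_width: float
    bins: np.ndarray  # (n_bins, 2) [lo, hi] um, ordered inward -> outward
    bin_index: np.ndarray  # int raster, -1 = unassigned
    pixel_size: float

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def mask(self, j: int) -> np.ndarray:
        return self.bin_index == j

    @property
    def n_pixels(self) -> np.ndarray:
        return np.bincount(
            self.bin_index[self.bin_index >= 0].ravel(), minlength=self.n_bins
        )

    @property
    def areas_um2(self) -> np.ndarray:
        return self.n_pixels * self.pixel_size**2

    @property
    def empty_bins(self) -> np.ndarray:
        """Flags for rings that received zero pixels."""
        return self.n_pixels == 0

    @property
    def outward(self) -> np.ndarray:
        """Boolean selector for bins outside the margin (lo >= 0)."""
        return self.bins[:, 0] >= 0


def build_rings(
    dmap: np.ndarray,
    ring_width: float = 8.0,
    extent: float = 296.0,
    exclusions: BinaryMask | np.ndarray | None = None,
    pixel_size: float = 1.0,
    lesion_id: int = 1,
) -> RingSet:
    """Bin a signed distance map into consecutive circumferential rings.

    Outward ring j covers ``((j-1)*w, j*w]`` um, symmetric inward on
    negative distances; ``extent`` must be an exact multiple of
    ``ring_width`` (no silent truncation).  ``exclusions`` removes pixels
    (other lesions' territory, off-section regions) from every ring.
    """
    if ring_width <= 0:
        raise ValueError("ring_width must be > 0")
    n = extent / ring_width
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"extent ({extent}) must be an integer multiple of ring_width ({ring_width})"
        )
    n = int(round(n))
    edges = np.arange(-n, n + 1) * ring_width
    bins = np.column_stack([edges[:-1], edges[1:]])

    # half-open (lo, hi]: searchsorted with side='left' on d over the edges
    idx = np.searchsorted(edges, dmap, side="left") - 1
    valid = (dmap > edges[0]) & (dmap <= edges[-1])
    if exclusions is not None:
        excl = exclusions.raster if isinstance(exclusions, BinaryMask) else exclusions
        valid &= ~np.asarray(excl, dtype=bool)
    bin_index = np.where(valid, idx, -1)

    rings = RingSet(
        lesion_id=lesion_id,
        ring_width=ring_width,
        bins=bins,
        bin_index=bin_index,
        pixel_size=pixel_size,
    )
    n_empty = int(rings.empty_bins.sum())
    if n_empty:
        logger.warning("lesion %d: %d of %d rings are empty", lesion_id, n_empty, 2 * n)
    return rings


def territory_exclusions(
    lesions: LesionSet,
    k: int,
    extent: float = 296.0,
    dmaps: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Pixels belonging to other lesions' tumor-or-BAT territory.

    A pixel is excluded from lesion k's rings when it lies inside another
    lesion's hull, or within ``extent`` of another lesion's margin while
    being nearer to that lesion than to lesion k (nearest-lesion
    assignment of contested BAT).
    """
    excl = np.zeros(lesions.labels.shape, dtype=bool)
    if lesions.n_lesions == 1:
        return excl
    dmaps = dmaps or {}
    dk = dmaps.get(k)
    if dk is None:
        dk = signed_distance_map(lesions, k)
    for j in lesions.lesion_ids:
        if j == k:
            continue
        dj = dmaps.get(int(j))
        if dj is None:
            dj = signed_distance_map(lesions, int(j))
        excl |= lesions.hull_mask(int(j))
        excl |= (dj > 0) & (dj <= extent) & (dj < dk)
    return excl


def contralateral_reference(
    section: SectionImage,
    lesions: LesionSet,
    k: int,
    tracer_channel: str = "tracer",
    extent: float = 296.0,
    min_pixels: int = 100,
    fallback_mask: BinaryMask | None = None,
) -> float:
    """Normal-brain reference intensity per unit area (AU/um^2).

    The lesion's tumor+BAT footprint is mirrored across the section's
    vertical midline; the mirrored pixels that avoid every lesion's
    tumor+BAT territory provide the reference.  If fewer than
    ``min_pixels`` survive, a user-supplied ``fallback_mask`` is used
    instead; with none supplied an error is raised.
    """
    tracer = np.asarray(section.channels[tracer_channel], dtype=float)
    dk = signed_distance_map(lesions, k)
    footprint = lesions.hull_mask(k) | ((dk > 0) & (dk <= extent))
    mirrored = footprint[:, ::-1]

    contaminated = np.zeros_like(mirrored)
    for j in lesions.lesion_ids:
        dj = signed_distance_map(lesions, int(j))
        contaminated |= lesions.hull_mask(int(j)) | ((dj > 0) & (dj <= extent))
    valid = mirrored & ~contaminated

    if valid.sum() < min_pixels:
        if fallback_mask is None:
            raise ValueError(
                f"mirrored reference for lesion {k} has {int(valid.sum())} clean "
                f"pixels (< {min_pixels}) and no fallback mask was supplied"
            )
        logger.warning("lesion %d: mirrored reference contaminated, using fallback", k)
        valid = fallback_mask.raster & ~contaminated
        if valid.sum() == 0:
            raise ValueError("fallback reference mask is empty after exclusions")

    pixel_area = section.pixel_size**2
    return float(tracer[valid].sum()) / (float(valid.sum()) * pixel_area)


def ring_statistics(
    rings: RingSet,
    tracer: np.ndarray,
    reference: float,
    pixel_size: float | None = None,
) -> RadialProfile:
    """Per-ring sum intensity per area and fold change vs the reference.

    Rings with zero pixels are omitted from the profile with a warning.
    """
    if reference <= 0:
        raise ValueError("reference must be > 0")
    tracer = np.asarray(tracer, dtype=float)
    px = rings.pixel_size if pixel_size is None else pixel_size
    pixel_area = px**2

    n_pix = rings.n_pixels
    sums = np.zeros(rings.n_bins)
    flat_idx = rings.bin_index.ravel()
    sel = flat_idx >= 0
    sums = np.bincount(flat_idx[sel], weights=tracer.ravel()[sel], minlength=rings.n_bins)

    keep = n_pix > 0
    if not keep.all():
        logger.warning(
            "omitting %d empty rings from profile", int((~keep).sum())
        )
    si_per_area = sums[keep] / (n_pix[keep] * pixel_area)
    return RadialProfile(
        bin_lo=rings.bins[keep, 0],
        bin_hi=rings.bins[keep, 1],
        n_pixels=n_pix[keep],
        value=si_per_area,
        units="au_per_um2",
        reference=reference,
        lesion_id=rings.lesion_id,
    )


def bat_mean_fold(profile: RadialProfile, window: tuple[float, float] = (0.0, 100.0)) -> float:
    """Pixel-weighted mean fold over outward bins inside the BAT window.

    A bin counts when its lower edge is >= ``window[0]`` and its upper
    edge is <= ``window[1]``; with 8-um rings and the default (0, 100]
    window that is the first 12 rings (up to 96 um).
    """
    lo, hi = window
    sel = (profile.bin_lo >= lo) & (profile.bin_hi <= hi) & (profile.n_pixels > 0)
    if not sel.any():
        raise ValueError(f"no rings inside window ({lo}, {hi}] um")
    w = profile.n_pixels[sel]
    return float(np.average(profile.fold[sel], weights=w))
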