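"""eGFP-based tumor segmentation.

Tumor pixels are defined by the binary-mask rule: eGFP intensity strictly
greater than ``fold_threshold`` (default 3) times a robust background
estimate.  Cancer-cell clusters whose boundaries lie within ``max_gap``
(default 100 um) of each other are merged into one lesion; the merged
lesion's *hull* (morphological closing + hole fill) defines the margin
from which signed distances are measured.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.morphology import disk

from .core import BinaryMask, LesionSet

__all__ = [
    "estimate_background",
    "tumor_mask",
    "merge_clusters",
    "merge_groups_bruteforce",
    "lesion_margin",
    "margin_mask",
    "build_hull",
]

# 8-connectivity for component labelling, 4-neighbourhood for margins
_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndi.generate_binary_structure(2, 1)


def estimate_background(egfp: np.ndarray, exclude: BinaryMask | None = None) -> float:
    """Median eGFP intensity outside ``exclude``, used as background B.

    The median is robust as long as tumor occupies a minority of pixels,
    so it can be called with no exclusion on a raw section.
    """
    egfp = np.asarray(egfp, dtype=float)
    if egfp.size == 0:
        raise ValueError("empty raster")
    if exclude is None:
        vals = egfp.ravel()
    else:
        keep = ~exclude.raster
        if keep.sum() < 0.1 * egfp.size:
            raise ValueError("fewer than 10% of pixels remain after exclusion")
        vals = egfp[keep]
    return float(np.median(vals))


def tumor_mask(
    egfp: np.ndarray,
    background: float,
    fold_threshold: float = 3.0,
    pixel_size: float = 1.0,
) -> BinaryMask:
    """Binary tumor mask: pixels strictly above ``fold_threshold * background``."""
    if background <= 0:
        raise ValueError("background must be > 0")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    egfp = np.asarray(egfp, dtype=float)
    return BinaryMask(egfp > fold_threshold * background, pixel_size)


def _boundary_4(mask: np.ndarray) -> np.ndarray:
    """Pixels of ``mask`` with at least one False 4-neighbour (or on the edge)."""
    interior = ndi.binary_erosion(mask, structure=_STRUCT4, border_value=0)
    return mask & ~interior


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n + 1))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)

    def groups(self, n: int) -> list[set[int]]:
        out: dict[int, set[int]] = {}
        for i in range(1, n + 1):
            out.setdefault(self.find(i), set()).add(i)
        return list(out.values())


def _merge_groups_edt(comp: np.ndarray, n_comp: int, max_gap_px: float) -> list[set[int]]:
    """Production merge: one EDT per component, sampled on the others' boundaries."""
    bounds = [_boundary_4(comp == i) for i in range(1, n_comp + 1)]
    uf = _UnionFind(n_comp)
    for i in range(n_comp):
        d = ndi.distance_transform_edt(~bounds[i])
        for j in range(i + 1, n_comp):
            if float(d[bounds[j]].min()) <= max_gap_px:
                uf.union(i + 1, j + 1)
    return uf.groups(n_comp)


def merge_groups_bruteforce(
    comp: np.ndarray, n_comp: int, max_gap_px: float
) -> list[set[int]]:
    """Brute-force oracle: explicit min over all boundary pixel pairs.

    Transitive closure of 'minimum pairwise boundary-to-boundary Euclidean
    distance <= max_gap_px', computed with ``cdist`` over boundary pixel
    coordinates.  Quadratic in boundary size; meant for small instances and
    as the independent reference for :func:`merge_clusters`.
    """
    coords = [np.argwhere(_boundary_4(comp == i)) for i in range(1, n_comp + 1)]
    uf = _UnionFind(n_comp)
    for i in range(n_comp):
        for j in range(i + 1, n_comp):
            if cdist(coords[i], coords[j]).min() <= max_gap_px:
                uf.union(i + 1, j + 1)
    return uf.groups(n_comp)


def build_hull(mask: np.ndarray, max_gap_px: float) -> np.ndarray:
    """Closed lesion footprint: closing with disk(max_gap/2) + hole fill."""
    radius = max(int(round(max_gap_px / 2.0)), 1)
    closed = ndi.binary_closing(mask, structure=disk(radius), border_value=0)
    return ndi.binary_fill_holes(closed | mask)


def merge_clusters(mask: BinaryMask, max_gap: float = 100.0) -> LesionSet:
    """Group cancer-cell clusters within ``max_gap`` um into one lesion.

    Connected components (8-connectivity) are merged by transitive closure
    of the exact minimum boundary-to-boundary Euclidean distance rule
    (<= ``max_gap``), evaluated with distance transforms.  Each merged
    lesion's hull is its morphological closing (disc of radius
    ``max_gap/2``) with interior holes filled; margins downstream are
    taken on the hull.
    """
    raster = mask.raster
    if not raster.any():
        raise ValueError("empty tumor mask")
    comp, n_comp = ndi.label(raster, structure=_STRUCT8)
    max_gap_px = max_gap / mask.pixel_size

    if n_comp == 1:
        groups = [{1}]
    else:
        groups = _merge_groups_edt(comp, n_comp, max_gap_px)

    # stable lesion numbering: by topmost-leftmost pixel of the group
    def group_key(g: set[int]) -> tuple[int, int]:
        rr, cc = np.nonzero(np.isin(comp, list(g)))
        i = np.lexsort((cc, rr))[0]
        return int(rr[i]), int(cc[i])

    groups = sorted(groups, key=group_key)

    labels = np.zeros_like(comp)
    hulls = np.zeros_like(comp)
    for k, g in enumerate(groups, start=1):
        gm = np.isin(comp, list(g))
        labels[gm] = k
        hull = build_hull(gm, max_gap_px)
        hulls[hull & (hulls == 0)] = k
    return LesionSet(labels=labels, hulls=hulls, pixel_size=mask.pixel_size)


def margin_mask(lesions: LesionSet, k: int) -> np.ndarray:
    """Boolean raster of lesion-``k`` hull pixels with a non-hull 4-neighbour."""
    hull = lesions.hull_mask(k)  # raises KeyError for unknown k
    m = _boundary_4(hull)
    if not m.any():  # cannot happen for a finite non-empty hull
        raise ValueError(f"lesion {k} has an empty margin")
    return m


def lesion_margin(lesions: LesionSet, k: int) -> np.ndarray:
    """Margin pixel coordinates of lesion ``k`` as an (N, 2) [row, col] array."""
    rr, cc = np.nonzero(margin_mask(lesions, k))
    return np.column_stack([rr, cc])
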