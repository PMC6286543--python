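"""Ground-truthed synthetic sections, autoradiographs, and blood curves.

The generator emulates the statistical structure the analysis assumes:
eGFP-bright lesions on dim tissue background, a tracer channel with a
tumor plateau and a halo decaying into the brain-adjacent-to-tumor (BAT)
band, Poisson + Gaussian camera noise, mono-exponential bolus blood
curves, and lesion-to-lesion heterogeneity.  Every output carries a
:class:`GroundTruth` so downstream recovery can be tested without any
real data.

Lesion tracer painting and the recorded true profile both use the same
margin definition as the analysis (hull of the rasterised lesion), so a
noiseless generate -> segment -> rings round trip is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import BinaryMask, BloodCurve, RadialProfile, SectionImage
from .segmentation import _boundary_4, build_hull

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "BloodCurveParams",
    "PlacementError",
    "generate_section",
    "generate_blood_curve",
    "generate_autoradiograph",
    "paclitaxel_step_profile",
    "DEFAULT_STANDARDS_NG_PER_G",
]

#: Default calibration-standard concentrations (ng/g); spans the expected
#: tissue range (1 ng/g distant brain up to the tumor plateau with headroom).
DEFAULT_STANDARDS_NG_PER_G = (1.0, 5.0, 20.0, 80.0, 250.0, 700.0)

#: Nominal BAT shell extent used for placement clearance and painting (um).
_SHELL_UM = 300.0


class PlacementError(RuntimeError):
    """Raised when lesion placement cannot satisfy the spacing invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic section generator.

    Distances in micrometres, intensities in arbitrary units (AU), folds
    dimensionless (>= 1).  Lesion centers are placed so that margins stay
    >= 2 x (300 um + max radius) apart and >= 300 um + radius from the
    image border, guaranteeing non-overlapping BAT shells; with
    ``mirror_clearance`` the lesions are additionally confined so their
    mirrored tumor+BAT footprints land in clean contralateral tissue.
    """

    image_shape: tuple[int, int] = (288, 640)  # (rows, cols) pixels
    pixel_size: float = 4.0  # um / pixel
    n_lesions: int = 1
    lesion_radius_range: tuple[float, float] = (120.0, 200.0)  # um
    egfp_background: float = 100.0  # AU
    egfp_tumor_fold: float = 5.0
    tracer_background: float = 50.0  # AU
    tumor_plateau_fold: float = 11.0
    bat_peak_fold: float = 2.5
    bat_decay_length: float = 60.0  # um (exponential) / step width (step)
    bat_profile_kind: str = "exponential"  # or "step"
    poisson_scale: float = 1.0  # photons per AU; 0 disables shot noise
    read_noise_sd: float = 2.0  # AU, additive Gaussian
    heterogeneity_cv: float = 0.2  # lesion-level lognormal CV
    shape_irregularity: float = 0.15  # harmonic amplitude, fraction of radius
    mirror_clearance: bool = True
    centers_um: list[tuple[float, float]] | None = None  # optional explicit (row, col)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for name in ("egfp_tumor_fold", "tumor_plateau_fold", "bat_peak_fold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.heterogeneity_cv < 0:
            raise ValueError("heterogeneity_cv must be >= 0")
        if self.bat_profile_kind not in ("exponential", "step"):
            raise ValueError("bat_profile_kind must be 'exponential' or 'step'")
        if not (0 <= self.shape_irregularity <= 0.2):
            raise ValueError("shape_irregularity must be in [0, 0.2]")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid lesion_radius_range")


@dataclass
class GroundTruth:
    """What the generator actually drew, for recovery tests."""

    lesion_labels: np.ndarray  # label raster on true lesion-mask pixels
    true_profile: RadialProfile  # noiseless nominal profile per distance bin
    lesion_factors: np.ndarray  # per-lesion heterogeneity multipliers
    true_kin_by_region: dict[str, float] | None = None  # mL/s/g
    calibration: tuple[float, float] | None = None  # (intercept AU, slope AU per ng/g)
    seed: int = 0


@dataclass
class BloodCurveParams:
    """Mono-exponential bolus blood curve parameters.

    ``duration`` matches the circulation endpoint (600 s for the
    fluorescent tracers, 28800 s for paclitaxel).
    """

    dose: float = 6.0  # mg/kg, bookkeeping only
    c0: float = 10.0  # amount per mL at t = 0
    half_life: float = 300.0  # s; may be np.inf
    duration: float = 600.0  # s
    n_samples: int = 121

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")


# ---------------------------------------------------------------------------
# lesion geometry

def _sample_radius_fn(rng: np.random.Generator, r0: float, irregularity: float):
    """Star-convex radius function r(theta) with low-order harmonics."""
    if irregularity == 0:
        return lambda theta: np.full_like(theta, r0, dtype=float)
    orders = np.array([2, 3, 4, 5])
    amps = rng.uniform(0, 1, size=orders.size)
    amps *= irregularity / max(amps.sum(), 1e-12)  # sum of |a_m| <= irregularity
    phases = rng.uniform(0, 2 * np.pi, size=orders.size)

    def radius(theta: np.ndarray) -> np.ndarray:
        pert = sum(a * np.cos(m * theta + p) for a, m, p in zip(amps, orders, phases))
        return r0 * (1.0 + pert)

    return radius


def _place_centers(cfg: GeneratorConfig, radii: np.ndarray, rng: np.random.Generator):
    """Rejection-sample lesion centers honouring the spacing invariants."""
    h_um = cfg.image_shape[0] * cfg.pixel_size
    w_um = cfg.image_shape[1] * cfg.pixel_size
    # harmonics enlarge the radius by up to shape_irregularity; clearances
    # must use the effective maximum so BAT shells stay inside the image
    bulge = 1.0 + cfg.shape_irregularity
    r_max = cfg.lesion_radius_range[1] * bulge
    min_margin_sep = 2 * (_SHELL_UM + r_max)

    if cfg.centers_um is not None:
        centers = [tuple(map(float, c)) for c in cfg.centers_um]
        if len(centers) != cfg.n_lesions:
            raise ValueError("centers_um length must equal n_lesions")
        return centers

    for _ in range(200):  # bounded restarts
        centers: list[tuple[float, float]] = []
        ok = True
        for i in range(cfg.n_lesions):
            border = _SHELL_UM + radii[i] * bulge + cfg.pixel_size
            row_lo, row_hi = border, h_um - border
            col_lo, col_hi = border, w_um - border
            if cfg.mirror_clearance:
                # whole tumor+BAT footprint in the left half => clean mirror
                col_hi = min(col_hi, w_um / 2 - (radii[i] * bulge + _SHELL_UM))
            if row_hi <= row_lo or col_hi <= col_lo:
                raise PlacementError(
                    "image too small for the requested lesion radius and clearances"
                )
            placed = False
            for _ in range(100):
                r = rng.uniform(row_lo, row_hi)
                c = rng.uniform(col_lo, col_hi)
                if all(
                    np.hypot(r - r2, c - c2) - (radii[i] + radii[j]) * bulge
                    >= min_margin_sep
                    for j, (r2, c2) in enumerate(centers)
                ):
                    centers.append((r, c))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return centers
    raise PlacementError(
        f"could not place {cfg.n_lesions} lesions with non-overlapping BAT shells"
    )


def _rasterize_lesions(cfg: GeneratorConfig, rng: np.random.Generator):
    """Labelled lesion mask + per-lesion hull, margin, and distance maps."""
    h, w = cfg.image_shape
    px = cfg.pixel_size
    r_lo, r_hi = cfg.lesion_radius_range
    radii = rng.uniform(r_lo, r_hi, size=cfg.n_lesions)
    centers = _place_centers(cfg, radii, rng)

    rows_um = np.arange(h)[:, None] * px
    cols_um = np.arange(w)[None, :] * px
    labels = np.zeros((h, w), dtype=np.int32)
    for k, ((cr, cc), r0) in enumerate(zip(centers, radii), start=1):
        radius_fn = _sample_radius_fn(rng, r0, cfg.shape_irregularity)
        dy = rows_um - cr
        dx = cols_um - cc
        rho = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)
        inside = rho <= radius_fn(theta)
        labels[inside] = k

    # signed distance to each lesion's hull margin, in um
    max_gap_px = 100.0 / px  # analysis-default hull, for paint consistency
    dmaps = np.full((cfg.n_lesions, h, w), np.inf)
    for k in range(1, cfg.n_lesions + 1):
        hull = build_hull(labels == k, max_gap_px)
        margin = _boundary_4(hull)
        d = ndi.distance_transform_edt(~margin) * px
        dmaps[k - 1] = np.where(hull, -d, d)
    return labels, dmaps


def _fold_profile(cfg: GeneratorConfig):
    """Nominal radial fold profile f(d) of signed distance d (um)."""
    plateau = cfg.tumor_plateau_fold
    peak = cfg.bat_peak_fold
    length = cfg.bat_decay_length

    def f(d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        out = np.ones_like(d)
        if cfg.bat_profile_kind == "exponential":
            halo = 1.0 + (peak - 1.0) * np.exp(-d / length)
            out = np.where((d > 0) & (d < _SHELL_UM), halo, out)
        else:  # step: constant elevation over (0, length]
            out = np.where((d > 0) & (d <= length), peak, out)
        out = np.where(d <= 0, plateau, out)
        return out

    return f


def _apply_noise(img: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator):
    out = img.astype(float)
    if cfg.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * cfg.poisson_scale) / cfg.poisson_scale
    if cfg.read_noise_sd > 0:
        out = out + rng.normal(0, cfg.read_noise_sd, size=out.shape)
    return out


def _lesion_factors(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Lognormal multipliers with mean 1 and CV = heterogeneity_cv."""
    if cfg.heterogeneity_cv == 0:
        return np.ones(cfg.n_lesions)
    sigma2 = np.log(1.0 + cfg.heterogeneity_cv**2)
    return rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=cfg.n_lesions)


def _binned_truth(
    value_map: np.ndarray,
    dmap_nearest: np.ndarray,
    territory: np.ndarray,
    ring_width: float,
    extent: float,
    units: str,
) -> RadialProfile:
    """Noiseless nominal per-bin means over the generated geometry."""
    n = int(round(extent / ring_width))
    edges = np.arange(-n, n + 1) * ring_width
    idx = np.searchsorted(edges, dmap_nearest, side="left") - 1
    sel = territory & (dmap_nearest > edges[0]) & (dmap_nearest <= edges[-1])
    counts = np.bincount(idx[sel], minlength=2 * n)
    sums = np.bincount(idx[sel], weights=value_map[sel], minlength=2 * n)
    keep = counts > 0
    bins = np.column_stack([edges[:-1], edges[1:]])
    return RadialProfile(
        bin_lo=bins[keep, 0],
        bin_hi=bins[keep, 1],
        n_pixels=counts[keep],
        value=sums[keep] / counts[keep],
        units=units,
        reference=1.0 if units == "fold" else None,
    )


def generate_section(
    config: GeneratorConfig,
    ring_width: float = 8.0,
    extent: float = 296.0,
) -> tuple[SectionImage, GroundTruth]:
    """Draw a two-channel section (eGFP + tracer) with known ground truth.

    The eGFP channel is flat background with lesion-mask pixels raised by
    ``egfp_tumor_fold``; the tracer channel is ``tracer_background`` times
    the configured radial fold profile of signed distance to the nearest
    lesion margin, with per-lesion heterogeneity on the enhancement; noise
    is applied last.  ``GroundTruth.true_profile`` records the noiseless
    nominal (heterogeneity-free) fold profile on the analysis binning.
    """
    rng = np.random.default_rng(config.seed)
    labels, dmaps = _rasterize_lesions(config, rng)
    factors = _lesion_factors(config, rng)
    f = _fold_profile(config)

    nearest = np.argmin(np.abs(dmaps), axis=0)
    d_nearest = np.take_along_axis(dmaps, nearest[None], axis=0)[0]

    fold_nom = f(d_nearest)
    fold_het = np.ones_like(fold_nom)
    territory = np.zeros(labels.shape, dtype=bool)
    for k in range(config.n_lesions):
        terr_k = (nearest == k) & (d_nearest <= _SHELL_UM)
        territory |= terr_k
        fold_het = np.where(
            terr_k, 1.0 + factors[k] * (fold_nom - 1.0), fold_het
        )

    egfp = np.full(labels.shape, config.egfp_background, dtype=float)
    egfp[labels > 0] *= config.egfp_tumor_fold
    tracer = config.tracer_background * fold_het

    section = SectionImage(
        channels={
            "egfp": _apply_noise(egfp, config, rng),
            "tracer": _apply_noise(tracer, config, rng),
        },
        pixel_size=config.pixel_size,
        id=f"synthetic-{config.seed}",
    )
    truth = GroundTruth(
        lesion_labels=labels,
        true_profile=_binned_truth(
            fold_nom, d_nearest, territory | (d_nearest > 0), ring_width, extent, "fold"
        ),
        lesion_factors=factors,
        seed=config.seed,
    )
    return section, truth


def generate_blood_curve(params: BloodCurveParams, tracer_id: str = "") -> BloodCurve:
    """Mono-exponential decay after an instantaneous bolus, sampled uniformly."""
    t = np.linspace(0.0, params.duration, params.n_samples)
    if np.isinf(params.half_life):
        c = np.full_like(t, params.c0)
    else:
        c = params.c0 * np.exp(-np.log(2.0) * t / params.half_life)
    return BloodCurve(times=t, concentrations=c, tracer_id=tracer_id)


def paclitaxel_step_profile(
    tumor: float = 529.0,
    bat_0_50: float = 86.7,
    bat_50_100: float = 35.4,
    distant: float = 1.0,
    extent: float = 300.0,
) -> RadialProfile:
    """Packaged step concentration profile (ng/g) for drug autoradiographs.

    Defaults encode the measured regional paclitaxel accumulation pattern:
    a high tumor plateau, a steeply decaying halo over the first 100 um of
    BAT, and a ~1 ng/g distant-brain baseline.
    """
    bin_lo = np.array([-extent, 0.0, 50.0, 100.0])
    bin_hi = np.array([0.0, 50.0, 100.0, extent])
    vals = np.array([tumor, bat_0_50, bat_50_100, distant])
    return RadialProfile(
        bin_lo=bin_lo,
        bin_hi=bin_hi,
        n_pixels=np.ones(4, dtype=int),
        value=vals,
        units="ng_per_g",
    )


def _profile_lookup(profile: RadialProfile):
    """Piecewise-constant c(d) from a binned profile; flat beyond support."""
    lo = profile.bin_lo
    hi = profile.bin_hi
    vals = profile.value
    baseline = float(vals[-1])

    def c(d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        out = np.full_like(d, baseline)
        out = np.where(d <= lo[0], vals[0], out)
        for l, h, v in zip(lo, hi, vals):
            out = np.where((d > l) & (d <= h), v, out)
        return out

    return c


def generate_autoradiograph(
    config: GeneratorConfig,
    profile_ng_per_g: RadialProfile,
    standards: tuple[float, ...] = DEFAULT_STANDARDS_NG_PER_G,
    gain: float = 20.0,
    offset: float = 50.0,
    strip_width_px: int = 16,
) -> tuple[SectionImage, GroundTruth, pd.DataFrame]:
    """Draw a single-channel phosphor raster plus calibration strip.

    Intensity is ``offset + gain * local ng/g`` plus the configured noise;
    a vertical strip along the left margin carries square patches at the
    standard concentrations.  The returned standards table holds each
    patch's nominal concentration and measured (noisy) mean intensity —
    exactly what calibration fitting consumes.  Lesion-level lognormal
    heterogeneity multiplies the concentration *enhancement* above the
    distant-brain baseline, so the baseline itself stays fixed.
    """
    standards = tuple(float(s) for s in standards)
    if len(standards) < 3:
        raise ValueError("need >= 3 calibration standards (curve unfittable)")
    if any(s <= 0 for s in standards):
        raise ValueError("standards must be strictly positive")

    rng = np.random.default_rng(config.seed)
    # keep lesion territory clear of the strip: widen the left border
    strip_um = strip_width_px * config.pixel_size
    cfg = replace(config, mirror_clearance=False)
    labels, dmaps = _rasterize_lesions_with_left_margin(cfg, rng, strip_um)
    factors = _lesion_factors(cfg, rng)

    nearest = np.argmin(np.abs(dmaps), axis=0)
    d_nearest = np.take_along_axis(dmaps, nearest[None], axis=0)[0]
    c_fn = _profile_lookup(profile_ng_per_g)
    c_nom = c_fn(d_nearest)
    baseline = float(profile_ng_per_g.value[-1])

    c_het = np.full_like(c_nom, baseline)
    territory = np.zeros(labels.shape, dtype=bool)
    for k in range(cfg.n_lesions):
        terr_k = (nearest == k) & (d_nearest <= _SHELL_UM)
        territory |= terr_k
        c_het = np.where(terr_k, baseline + factors[k] * (c_nom - baseline), c_het)

    intensity = offset + gain * c_het

    # calibration strip: stacked square patches over the left margin
    h, w = cfg.image_shape
    patch = max(strip_width_px - 4, 4)
    gap = 4
    rows_needed = len(standards) * (patch + gap)
    if rows_needed > h:
        raise ValueError("image too short for the calibration strip")
    patch_slices = []
    for i, s in enumerate(standards):
        r0 = 2 + i * (patch + gap)
        sl = (slice(r0, r0 + patch), slice(2, 2 + patch))
        intensity[sl] = offset + gain * s
        patch_slices.append(sl)

    noisy = _apply_noise(intensity, cfg, rng)
    measured = [float(noisy[sl].mean()) for sl in patch_slices]
    standards_df = pd.DataFrame(
        {"concentration_ng_per_g": standards, "intensity": measured}
    )

    section = SectionImage(
        channels={"autorad": noisy},
        pixel_size=cfg.pixel_size,
        id=f"synthetic-autorad-{cfg.seed}",
    )
    truth = GroundTruth(
        lesion_labels=labels,
        true_profile=profile_ng_per_g,
        lesion_factors=factors,
        calibration=(offset, gain),
        seed=cfg.seed,
    )
    return section, truth, standards_df


def _rasterize_lesions_with_left_margin(
    cfg: GeneratorConfig, rng: np.random.Generator, extra_left_um: float
):
    """Rasterise lesions keeping their BAT shells clear of the left strip."""
    if cfg.centers_um is None:
        # place on a virtual image missing the strip columns, then shift
        # the rasterised lesions right by the strip width
        strip_px = int(np.ceil(extra_left_um / cfg.pixel_size))
        virtual = replace(
            cfg, image_shape=(cfg.image_shape[0], cfg.image_shape[1] - strip_px)
        )
        labels_v, _ = _rasterize_lesions(virtual, rng)
        labels = np.zeros(cfg.image_shape, dtype=labels_v.dtype)
        labels[:, strip_px:] = labels_v
    else:
        return _rasterize_lesions(cfg, rng)

    px = cfg.pixel_size
    max_gap_px = 100.0 / px
    dmaps = np.full((cfg.n_lesions,) + cfg.image_shape, np.inf)
    for k in range(1, cfg.n_lesions + 1):
        hull = build_hull(labels == k, max_gap_px)
        margin = _boundary_4(hull)
        d = ndi.distance_transform_edt(~margin) * px
        dmaps[k - 1] = np.where(hull, -d, d)
    return labels, dmaps
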