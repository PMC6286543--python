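"""Unidirectional blood-to-tissue transfer constant (K_in) estimation.

The single-time uptake method divides the terminal tissue amount per gram
by the blood concentration-time integral:

    K_in = C_br(T) / integral_0^T C_bl(t) dt        [mL / s / g]

One terminal measurement per subject and region replaces a multi-time
regression, which is the appropriate choice when lesions are too
heterogeneous to pool across animals.  Values are conventionally reported
on a 1e-5 mL/s/g scale (see ``KIN_REPORT_SCALE``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BloodCurve, TissueUptake

__all__ = [
    "KIN_REPORT_SCALE",
    "KinResult",
    "RegionComparison",
    "blood_auc",
    "kin_single_time",
    "kin_by_region",
    "compare_regions",
]

logger = logging.getLogger(__name__)

#: Reporting scale for K_in tables: values are printed as K_in / 1e-5.
KIN_REPORT_SCALE = 1e-5

REGION_ORDER = ("normal", "bat", "tumor")


@dataclass
class KinResult:
    """Per-region K_in summary across subjects (mL/s/g)."""

    region: str
    kin_values: np.ndarray  # per-subject, mL/s/g
    mean: float
    sem: float | None  # None when n == 1

    @property
    def n(self) -> int:
        return int(np.asarray(self.kin_values).size)

    @property
    def mean_1e5(self) -> float:
        """Mean on the conventional 1e-5 mL/s/g reporting scale."""
        return self.mean / KIN_REPORT_SCALE

    @property
    def sem_1e5(self) -> float | None:
        return None if self.sem is None else self.sem / KIN_REPORT_SCALE


def blood_auc(curve: BloodCurve, t_end: float) -> float:
    """Trapezoidal integral of the blood curve over [0, t_end].

    ``t_end`` must not exceed the last sample time (no extrapolation); an
    interior ``t_end`` is handled by linear interpolation of the final
    partial interval.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if t_end > curve.times[-1] + 1e-12:
        raise ValueError(
            f"t_end ({t_end}) beyond last blood sample ({curve.times[-1]}); "
            "refusing to extrapolate"
        )
    t, c = curve.times, curve.concentrations
    inside = t <= t_end
    tt = t[inside]
    cc = c[inside]
    if tt[-1] < t_end:  # close the interval at t_end by interpolation
        c_end = float(np.interp(t_end, t, c))
        tt = np.append(tt, t_end)
        cc = np.append(cc, c_end)
    return float(np.trapezoid(cc, tt))


def kin_single_time(uptake: TissueUptake, curve: BloodCurve) -> float:
    """Single-time-uptake K_in = C_br(T) / AUC_blood(0, T), in mL/s/g."""
    auc = blood_auc(curve, uptake.t_end)
    if auc <= 0:
        raise ValueError("blood AUC is zero over [0, T]; K_in undefined")
    return uptake.c_br / auc


def kin_by_region(
    uptakes: list[TissueUptake], curve: BloodCurve
) -> dict[str, KinResult]:
    """Per-region mean +/- SEM of per-subject K_in.

    Regions with no subjects are omitted with a warning; a single-subject
    region reports its value with SEM ``None``.
    """
    by_region: dict[str, list[float]] = {}
    for u in uptakes:
        by_region.setdefault(u.region, []).append(kin_single_time(u, curve))

    results: dict[str, KinResult] = {}
    regions = [r for r in REGION_ORDER if r in by_region]
    regions += [r for r in by_region if r not in REGION_ORDER]
    for region in regions:
        vals = np.asarray(by_region[region], dtype=float)
        sem = float(stats.sem(vals)) if vals.size > 1 else None
        results[region] = KinResult(
            region=region, kin_values=vals, mean=float(vals.mean()), sem=sem
        )
    missing = [r for r in REGION_ORDER if r not in results]
    if missing:
        logger.warning("no subjects for region(s): %s", ", ".join(missing))
    return results


@dataclass
class RegionComparison:
    """One-way ANOVA across regions with Holm-Sidak pairwise follow-up."""

    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # group_a, group_b, t, p_raw, p_adj, significant
    alpha: float = 0.05
    method: str = "one-way ANOVA + Holm-Sidak pairwise t-tests"

    @property
    def significant(self) -> bool:
        return bool(self.anova_p < self.alpha)


def compare_regions(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> RegionComparison:
    """One-way ANOVA over per-subject K_in groups, pairwise Holm-Sidak.

    ``groups`` maps region name to the vector of per-subject K_in values.
    With every observation identical the variance is degenerate; p is
    then reported as 1 with a warning instead of NaN.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if np.asarray(vals).size < 2:
            raise ValueError(f"group '{name}' needs >= 2 subjects")

    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    allvals = np.concatenate(list(arrays.values()))
    degenerate = np.ptp(allvals) == 0
    if degenerate:
        logger.warning("all observations identical; reporting p = 1")
        f_stat, p_val = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-within-group warnings
            f_stat, p_val = stats.f_oneway(*arrays.values())
        if np.isnan(p_val):
            f_stat, p_val = 0.0, 1.0

    names = list(arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[names[i]], arrays[names[j]]
            if np.ptp(np.concatenate([a, b])) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append(
                {"group_a": names[i], "group_b": names[j], "t": float(t), "p_raw": float(p)}
            )
    pairwise = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(
        pairwise["p_raw"].to_numpy(), alpha=alpha, method="holm-sidak"
    )
    pairwise["p_adj"] = p_adj
    pairwise["significant"] = reject

    return RegionComparison(
        anova_f=float(f_stat), anova_p=float(p_val), pairwise=pairwise, alpha=alpha
    )
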