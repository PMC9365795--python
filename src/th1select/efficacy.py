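"""Preclinical vaccine-efficacy quantification.

Caliper measurements (length × width × height, mm) are converted to tumor
volumes with the ellipsoid coefficient 0.5236 (= π/6).  Treatment arms are
compared with a two-way ANOVA (arm × day, day categorical) and Dunnett-style
contrasts of each arm against the adjuvant control; the headline effect size
is percent inhibition, 100 × (1 − treated mean / control mean).  Growth
curves convert to survival records by the termination rule — a mouse exits
the study when its tumor first reaches 2000 mm³ — with administrative
censoring at the 115-day horizon, after which the Kaplan–Meier product-limit
estimator and Fisher's exact test on horizon proportions summarize survival.
A noncentral-t power calculator reproduces group-size planning for the
two-sided two-sample design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.power import TTestIndPower

__all__ = [
    "VOLUME_COEFFICIENT",
    "MouseCurve",
    "TumorStudy",
    "SurvivalRecord",
    "GroupComparison",
    "GrowthComparison",
    "tumor_volume",
    "percent_inhibition",
    "compare_growth",
    "to_survival",
    "km_estimate",
    "fisher_exact",
    "group_size",
    "read_measurements",
    "survival_frame",
]

#: ellipsoid volume coefficient for caliper length × width × height (π/6)
VOLUME_COEFFICIENT = 0.5236


def tumor_volume(length: float, width: float, height: float) -> float:
    """Tumor volume in mm³ from three caliper dimensions in mm.

    volume = length × width × height × 0.5236; symmetric in its arguments.
    """
    for name, v in (("length", length), ("width", width), ("height", height)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return length * width * height * VOLUME_COEFFICIENT


def percent_inhibition(control_mean: float, treated_mean: float) -> float:
    """Percent tumor-growth inhibition: 100 × (1 − treated / control).

    Negative when the treated mean exceeds the control mean.
    """
    if control_mean <= 0:
        raise ValueError(f"control_mean must be > 0, got {control_mean}")
    if treated_mean < 0:
        raise ValueError(f"treated_mean must be >= 0, got {treated_mean}")
    return 100.0 * (1.0 - treated_mean / control_mean)


@dataclass(frozen=True)
class MouseCurve:
    """One mouse's growth curve: tumor volume (mm³) at strictly increasing days."""

    mouse_id: str
    days: tuple[float, ...]
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.days)
        vols = tuple(float(v) for v in self.volumes)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "volumes", vols)
        if len(days) == 0:
            raise ValueError(f"mouse {self.mouse_id}: no measurements")
        if len(days) != len(vols):
            raise ValueError(f"mouse {self.mouse_id}: days/volumes length mismatch")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"mouse {self.mouse_id}: days not strictly increasing")
        if any(v < 0 for v in vols):
            raise ValueError(f"mouse {self.mouse_id}: negative volume")


@dataclass
class TumorStudy:
    """Growth curves grouped by treatment arm, with the study's stopping rules."""

    arms: dict[str, list[MouseCurve]]
    termination_volume: float = 2000.0
    horizon_day: float = 115.0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for arm, curves in self.arms.items():
            for c in curves:
                if c.mouse_id in seen:
                    raise ValueError(f"mouse {c.mouse_id} appears in more than one arm")
                seen.add(c.mouse_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, curves in self.arms.items():
            for c in curves:
                for d, v in zip(c.days, c.volumes):
                    rows.append((c.mouse_id, arm, d, v))
        return pd.DataFrame(rows, columns=["mouse", "arm", "day", "volume"])


@dataclass(frozen=True)
class SurvivalRecord:
    mouse_id: str
    arm: str
    time: float  # day of event or censoring
    event: bool  # True = tumor reached the termination volume


@dataclass
class GroupComparison:
    """One treated arm's contrast against the control arm."""

    arm: str
    mean_difference: float  # treated − control per-mouse mean volume
    p_unadjusted: float
    p_adjusted: float


@dataclass
class GrowthComparison:
    """Result of a growth-curve group comparison."""

    control_arm: str
    per_day: pd.DataFrame  # arm, day, n, mean_volume, sem
    contrasts: list[GroupComparison]
    p_treatment: float
    p_day: float
    p_interaction: float
    method: str = "dunnett"
    extra: dict = field(default_factory=dict)


def _per_day_stats(df: pd.DataFrame) -> pd.DataFrame:
    # SEM over mice alive and measured that day; no carry-forward
    g = df.groupby(["arm", "day"])["volume"]
    out = g.agg(n="count", mean_volume="mean", sem=lambda x: x.std(ddof=1) / math.sqrt(len(x)))
    return out.reset_index()


def compare_growth(
    study: TumorStudy, control_arm: str, method: str = "dunnett"
) -> GrowthComparison:
    """Two-way ANOVA (arm × day) plus contrasts of each arm vs the control.

    The ANOVA treats day as a categorical factor with interaction on the
    per-measurement volumes.  Because terminated mice drop out of later
    means (no carry-forward), the analysis window is restricted to days up
    to the earliest mouse's last measurement, so every mouse contributes to
    every analyzed day.  Contrasts are computed on each mouse's mean volume
    over that window (the mouse is the experimental unit) and adjusted for
    multiplicity against the single control with Dunnett's procedure
    (``method="bonferroni"`` gives the conservative fallback).  The per-day
    means ± SEM table is not windowed; it covers every measured day.
    """
    if control_arm not in study.arms:
        raise ValueError(f"control arm {control_arm!r} not in study")
    if len(study.arms) < 2:
        raise ValueError("need at least two arms to compare")
    for arm, curves in study.arms.items():
        if len(curves) < 2:
            raise ValueError(f"arm {arm!r} has fewer than 2 mice")

    df = study.to_frame()
    last_full_day = df.groupby("mouse")["day"].max().min()
    win = df[df["day"] <= last_full_day]

    # overall two-factor analysis on the fully observed window
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if win["day"].nunique() >= 2:
            model = ols("volume ~ C(arm) * C(day)", data=win).fit()
            table = anova_lm(model, typ=2)
            p_treatment = float(table.loc["C(arm)", "PR(>F)"])
            p_day = float(table.loc["C(day)", "PR(>F)"])
            p_interaction = float(table.loc["C(arm):C(day)", "PR(>F)"])
        else:
            model = ols("volume ~ C(arm)", data=win).fit()
            table = anova_lm(model, typ=2)
            p_treatment = float(table.loc["C(arm)", "PR(>F)"])
            p_day = math.nan
            p_interaction = math.nan

    # per-mouse summary for the arm contrasts
    mouse_means = win.groupby(["arm", "mouse"])["volume"].mean()
    control = mouse_means.loc[control_arm].to_numpy()
    treated_arms = sorted(a for a in study.arms if a != control_arm)
    samples = [mouse_means.loc[a].to_numpy() for a in treated_arms]

    k = len(samples)
    p_unadj = []
    # noise-free synthetic curves give (near-)zero within-group variance;
    # treat those contrasts deterministically instead of relying on a t ratio
    def _degenerate(s):
        return np.var(s, ddof=1) < 1e-12 * max(1.0, np.mean(s) ** 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for s in samples:
            if _degenerate(s) and _degenerate(control):
                p_unadj.append(1.0 if np.isclose(np.mean(s), np.mean(control)) else 0.0)
            else:
                p_unadj.append(float(stats.ttest_ind(s, control, equal_var=True).pvalue))

        all_degenerate = all(_degenerate(g) for g in samples + [control])
        if all_degenerate:
            p_adj = [1.0 if np.isclose(np.mean(s), np.mean(control)) else 0.0
                     for s in samples]
        elif method == "dunnett":
            # the multivariate-t tail probability is evaluated by randomized
            # quadrature; a fixed internal seed keeps results reproducible
            res = stats.dunnett(*samples, control=control, rng=180580)
            p_adj = [float(p) for p in res.pvalue]
        elif method == "bonferroni":
            p_adj = [min(1.0, k * p) for p in p_unadj]
        else:
            raise ValueError(f"unknown method: {method!r}")
    # adjustment never reports stronger evidence than the raw contrast
    p_adj = [max(pa, pu) for pa, pu in zip(p_adj, p_unadj)]

    contrasts = [
        GroupComparison(
            arm=a,
            mean_difference=float(np.mean(s) - np.mean(control)),
            p_unadjusted=pu,
            p_adjusted=pa,
        )
        for a, s, pu, pa in zip(treated_arms, samples, p_unadj, p_adj)
    ]
    return GrowthComparison(
        control_arm=control_arm,
        per_day=_per_day_stats(df),
        contrasts=contrasts,
        p_treatment=p_treatment,
        p_day=p_day,
        p_interaction=p_interaction,
        method=method,
        extra={"last_full_day": float(last_full_day)},
    )


def _crossing_time(curve: MouseCurve, threshold: float) -> Optional[float]:
    """First day the volume reaches the threshold; linear interpolation in
    volume between measurement days.  "Reached" is inclusive."""
    days, vols = curve.days, curve.volumes
    for i, v in enumerate(vols):
        if v >= threshold:
            if i == 0 or vols[i] == vols[i - 1]:
                return days[i]
            if vols[i - 1] >= threshold:  # cannot happen (first crossing), guard
                return days[i - 1]
            frac = (threshold - vols[i - 1]) / (vols[i] - vols[i - 1])
            return days[i - 1] + frac * (days[i] - days[i - 1])
    return None


def to_survival(study: TumorStudy) -> list[SurvivalRecord]:
    """Convert growth curves to survival records via the termination rule.

    Event time is the first (linearly interpolated) day the volume reaches
    the termination volume; mice never reaching it by the horizon are
    administratively censored at the horizon day.
    """
    records = []
    for arm, curves in study.arms.items():
        for c in curves:
            t = _crossing_time(c, study.termination_volume)
            if t is None or t > study.horizon_day:
                records.append(SurvivalRecord(c.mouse_id, arm, study.horizon_day, False))
            else:
                records.append(SurvivalRecord(c.mouse_id, arm, t, True))
    return records


def km_estimate(records: Sequence[SurvivalRecord]) -> dict[str, pd.DataFrame]:
    """Kaplan–Meier product-limit survival per arm.

    Returns, per arm, a DataFrame with columns ``time`` and ``survival``
    (the step function evaluated at the observed times).  With no censoring
    before an evaluation time the estimate equals the empirical surviving
    fraction.
    """
    if not records:
        raise ValueError("no survival records")
    out: dict[str, pd.DataFrame] = {}
    by_arm: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        by_arm.setdefault(r.arm, []).append(r)
    for arm in sorted(by_arm):
        recs = by_arm[arm]
        kmf = KaplanMeierFitter()
        kmf.fit([r.time for r in recs], [r.event for r in recs])
        sf = kmf.survival_function_
        out[arm] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        })
    return out


def survival_at(records: Sequence[SurvivalRecord], t: float) -> dict[str, float]:
    """KM survival probability per arm evaluated at time ``t``."""
    out = {}
    for arm, tbl in km_estimate(records).items():
        mask = tbl["time"] <= t
        out[arm] = float(tbl.loc[mask, "survival"].iloc[-1]) if mask.any() else 1.0
    return out


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 count table.

    Sums hypergeometric probabilities of tables (at fixed margins) no more
    likely than the observed one.  A table with an all-zero margin carries no
    information: p = 1.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise ValueError("table entries must be non-negative integers")
        arr = arr.astype(int)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


def group_size(
    effect_size_d: float, alpha: float = 0.05, power: float = 0.8, max_n: int = 100000
) -> int:
    """Smallest per-group n for a two-sided two-sample t-test.

    Power is computed from the noncentral-t distribution (equal group sizes,
    standardized difference ``effect_size_d``).
    """
    if effect_size_d <= 0:
        raise ValueError("effect_size_d must be > 0")
    if not (0 < power < 1):
        raise ValueError("power must be in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    solver = TTestIndPower()
    n = 2
    while n <= max_n:
        achieved = solver.power(effect_size=effect_size_d, nobs1=n, alpha=alpha,
                                ratio=1.0, alternative="two-sided")
        if achieved >= power:
            return n
        n += 1
    raise ValueError(
        f"no group size up to {max_n} reaches power {power} at d={effect_size_d}"
    )


def read_measurements(
    path, termination_volume: float = 2000.0, horizon_day: float = 115.0
) -> TumorStudy:
    """Read caliper CSV ``mouse,arm,day,length_mm,width_mm,height_mm`` into a study."""
    df = pd.read_csv(path)
    required = ["mouse", "arm", "day", "length_mm", "width_mm", "height_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    df["volume"] = [
        tumor_volume(l, w, h)
        for l, w, h in zip(df["length_mm"], df["width_mm"], df["height_mm"])
    ]
    arms: dict[str, list[MouseCurve]] = {}
    for (arm, mouse), grp in df.groupby(["arm", "mouse"], sort=True):
        grp = grp.sort_values("day")
        arms.setdefault(str(arm), []).append(
            MouseCurve(str(mouse), tuple(grp["day"]), tuple(grp["volume"]))
        )
    return TumorStudy(arms, termination_volume=termination_volume,
                      horizon_day=horizon_day)


def survival_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "mouse": [r.mouse_id for r in records],
        "arm": [r.arm for r in records],
        "time": [r.time for r in records],
        "event": [r.event for r in records],
    })
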