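"""Seeded synthetic-data generators for every pipeline stage.

Three generators emulate the statistical structure of the study's inputs so
the whole chain is testable without any external download:

* :func:`gen_gene_table` — per-gene differential-expression summaries with a
  planted set of true candidates (upregulated in both Gleason strata, PIN
  evidence, tumor-line expression) among nulls constructed to fail at least
  one filter.
* :func:`gen_elispot_cohort` — well-level ELISPOT counts for a donor cohort:
  each donor is a responder with an epitope- and cytokine-specific
  probability; spot counts are Poisson (optionally negative binomial) around
  a responder or background mean, with 4-replicate experimental and
  no-antigen control wells.
* :func:`gen_tumor_study` — exponential tumor growth with multiplicative
  per-arm rate effects and lognormal measurement noise on an alternating
  2/3-day caliper grid, truncated after the 2000 mm³ termination volume is
  crossed.

All generators are deterministic given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .efficacy import VOLUME_COEFFICIENT, MouseCurve, TumorStudy
from .elispot import Cytokine
from .funnel import GeneRecord
from .selectivity import Label

__all__ = [
    "CytokineProfile",
    "EpitopeProfile",
    "GrowthModel",
    "gen_gene_table",
    "planted_symbols",
    "gen_elispot_cohort",
    "gen_tumor_study",
    "study_to_measurements_frame",
    "strong_th1_profile",
    "il10_only_profile",
    "null_profile",
    "mixed_profile",
    "default_epitope_panel",
    "calibrated_tumor_arms",
]

PLANTED_PREFIX = "CAND"
NULL_PREFIX = "NULL"


@dataclass(frozen=True)
class CytokineProfile:
    """Donor-level response model for one cytokine.

    A donor responds with probability ``response_probability``; responding
    donors' experimental wells have mean ``responder_mean_spots`` while
    non-responders' experimental wells and everyone's control wells have mean
    ``background_mean_spots``.
    """

    response_probability: float
    responder_mean_spots: float
    background_mean_spots: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.response_probability <= 1.0):
            raise ValueError("response_probability must be in [0, 1]")
        if self.background_mean_spots < 0:
            raise ValueError("background_mean_spots must be >= 0")
        if self.response_probability > 0 and not (
            self.responder_mean_spots > self.background_mean_spots
        ):
            # a "responding" cytokine must actually raise the mean
            raise ValueError("responder_mean_spots must exceed background_mean_spots")


@dataclass(frozen=True)
class EpitopeProfile:
    epitope_id: str
    ifng: CytokineProfile
    il10: CytokineProfile
    intended_label: Optional[Label] = None

    def profile_for(self, cytokine: Cytokine) -> CytokineProfile:
        return self.ifng if cytokine == Cytokine.IFNG else self.il10


@dataclass(frozen=True)
class GrowthModel:
    """Exponential tumor growth V(t) = V0 · exp(arm_effect · r · t) · noise.

    ``noise_cv`` is the coefficient of variation of multiplicative lognormal
    measurement noise (mean 1); ``measurement_interval`` is the alternating
    caliper schedule in days.
    """

    baseline_volume: float = 5.0  # mm^3 at implant
    growth_rate: float = 0.116  # per day
    arm_effect: float = 1.0
    noise_cv: float = 0.3
    measurement_interval: tuple[int, ...] = (2, 3)

    def __post_init__(self) -> None:
        if self.baseline_volume <= 0 or self.growth_rate <= 0 or self.arm_effect <= 0:
            raise ValueError("baseline_volume, growth_rate and arm_effect must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.measurement_interval:
            raise ValueError("measurement_interval must be non-empty")


def gen_gene_table(
    n_genes: int,
    n_true_candidates: int,
    seed: int,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    pin_prob: float = 1.0,
) -> list[GeneRecord]:
    """Generate a DE summary table with a planted candidate set.

    Planted genes (symbols ``CAND_*``) pass the upregulation rule in both
    strata and carry PIN evidence with probability ``pin_prob`` and
    tumor-line expression; null genes (``NULL_*``) are constructed to fail at
    least one differential-expression criterion.  Rows are shuffled
    deterministically.
    """
    if n_true_candidates < 0 or n_genes < n_true_candidates:
        raise ValueError("need 0 <= n_true_candidates <= n_genes")
    if n_genes == 0:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[GeneRecord] = []
    for i in range(n_true_candidates):
        records.append(GeneRecord(
            gene_symbol=f"{PLANTED_PREFIX}_{i + 1:03d}",
            log2fc_low=float(rng.uniform(lfc_threshold + 0.5, lfc_threshold + 3.0)),
            fdr_low=float(rng.uniform(1e-8, fdr_threshold * 0.5)),
            log2fc_high=float(rng.uniform(lfc_threshold + 0.5, lfc_threshold + 3.0)),
            fdr_high=float(rng.uniform(1e-8, fdr_threshold * 0.5)),
            pin_evidence=bool(rng.random() < pin_prob),
            tumor_line_expressed=True,
        ))
    # null failure modes: weak effect, non-significant, or discordant strata
    modes = rng.integers(0, 4, size=n_genes - n_true_candidates)
    for i, mode in enumerate(modes):
        lfc_lo = float(rng.uniform(lfc_threshold + 0.5, lfc_threshold + 3.0))
        lfc_hi = float(rng.uniform(lfc_threshold + 0.5, lfc_threshold + 3.0))
        fdr_lo = float(rng.uniform(1e-8, fdr_threshold * 0.5))
        fdr_hi = float(rng.uniform(1e-8, fdr_threshold * 0.5))
        if mode == 0:  # weak in the low stratum
            lfc_lo = float(rng.uniform(-1.0, lfc_threshold))
        elif mode == 1:  # not significant in the low stratum
            fdr_lo = float(rng.uniform(fdr_threshold, 1.0))
        elif mode == 2:  # weak in the high stratum only (discordant)
            lfc_hi = float(rng.uniform(-1.0, lfc_threshold))
        else:  # not significant in the high stratum only
            fdr_hi = float(rng.uniform(fdr_threshold, 1.0))
        records.append(GeneRecord(
            gene_symbol=f"{NULL_PREFIX}_{i + 1:04d}",
            log2fc_low=lfc_lo,
            fdr_low=fdr_lo,
            log2fc_high=lfc_hi,
            fdr_high=fdr_hi,
            pin_evidence=bool(rng.random() < 0.3),
            tumor_line_expressed=bool(rng.random() < 0.5),
        ))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def planted_symbols(records: Sequence[GeneRecord]) -> set[str]:
    """Symbols of the planted true candidates in a generated table."""
    return {r.gene_symbol for r in records
            if r.gene_symbol.startswith(PLANTED_PREFIX)}


def _draw_counts(rng, mean: float, size: int, dispersion: Optional[float]) -> np.ndarray:
    if mean == 0:
        return np.zeros(size, dtype=int)
    if dispersion is None:
        return rng.poisson(mean, size=size)
    # negative binomial with var = mean + mean^2 / dispersion
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def gen_elispot_cohort(
    n_donors: int,
    profiles: Sequence[EpitopeProfile],
    seed: int,
    n_replicates: int = 4,
    cells_per_well: int = 200_000,
    dispersion: Optional[float] = None,
) -> pd.DataFrame:
    """Generate a well-level ELISPOT table for a donor cohort.

    Returns one row per well with columns ``donor, epitope, cytokine,
    well_type, replicate, spots, cells_per_well``.  Poisson counts by
    default; pass ``dispersion`` for negative-binomial overdispersion.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    donors = [f"D{i + 1:02d}" for i in range(n_donors)]
    for profile in profiles:
        for donor in donors:
            for cytokine in (Cytokine.IFNG, Cytokine.IL10):
                cp = profile.profile_for(cytokine)
                responder = rng.random() < cp.response_probability
                exp_mean = cp.responder_mean_spots if responder else cp.background_mean_spots
                exp = _draw_counts(rng, exp_mean, n_replicates, dispersion)
                ctl = _draw_counts(rng, cp.background_mean_spots, n_replicates, dispersion)
                for rep in range(n_replicates):
                    rows.append((donor, profile.epitope_id, cytokine.value,
                                 "experimental", rep + 1, int(exp[rep]), cells_per_well))
                for rep in range(n_replicates):
                    rows.append((donor, profile.epitope_id, cytokine.value,
                                 "control", rep + 1, int(ctl[rep]), cells_per_well))
    return pd.DataFrame(
        rows,
        columns=["donor", "epitope", "cytokine", "well_type", "replicate",
                 "spots", "cells_per_well"],
    )


def _measurement_grid(model: GrowthModel, horizon_day: float) -> list[float]:
    grid = [0.0]
    i = 0
    while True:
        nxt = grid[-1] + model.measurement_interval[i % len(model.measurement_interval)]
        if nxt > horizon_day:
            break
        grid.append(float(nxt))
        i += 1
    return grid


def gen_tumor_study(
    arms: dict[str, tuple[int, GrowthModel]],
    seed: int,
    horizon_day: float = 115.0,
    termination_volume: float = 2000.0,
) -> TumorStudy:
    """Generate per-mouse exponential growth curves grouped by arm.

    Each mouse's curve is sampled on the caliper grid and truncated after
    its first measurement at or above the termination volume (the mouse
    exits the study at that measurement).
    """
    rng = np.random.default_rng(seed)
    study_arms: dict[str, list[MouseCurve]] = {}
    for arm in sorted(arms):
        n_mice, model = arms[arm]
        if n_mice < 1:
            raise ValueError(f"arm {arm!r}: n_mice must be >= 1")
        grid = np.array(_measurement_grid(model, horizon_day))
        if model.noise_cv > 0:
            sigma = float(np.sqrt(np.log(1.0 + model.noise_cv ** 2)))
        else:
            sigma = 0.0
        curves = []
        for m in range(n_mice):
            mean_curve = model.baseline_volume * np.exp(
                model.arm_effect * model.growth_rate * grid
            )
            if sigma > 0:
                noise = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma,
                                      size=grid.size)
            else:
                noise = np.ones(grid.size)
            vols = mean_curve * noise
            crossed = np.nonzero(vols >= termination_volume)[0]
            last = crossed[0] if crossed.size else grid.size - 1
            curves.append(MouseCurve(
                mouse_id=f"{arm}-m{m + 1:02d}",
                days=tuple(grid[: last + 1]),
                volumes=tuple(vols[: last + 1]),
            ))
        study_arms[arm] = curves
    return TumorStudy(study_arms, termination_volume=termination_volume,
                      horizon_day=horizon_day)


def study_to_measurements_frame(study: TumorStudy) -> pd.DataFrame:
    """Express a study as a caliper CSV table (cubic dimensions recover the volume)."""
    rows = []
    for arm in sorted(study.arms):
        for c in study.arms[arm]:
            for d, v in zip(c.days, c.volumes):
                dim = (v / VOLUME_COEFFICIENT) ** (1.0 / 3.0)
                rows.append((c.mouse_id, arm, d, dim, dim, dim))
    return pd.DataFrame(
        rows, columns=["mouse", "arm", "day", "length_mm", "width_mm", "height_mm"]
    )


# ---------------------------------------------------------------------------
# canonical profiles and scenarios used throughout the tests and examples

def strong_th1_profile(epitope_id: str = "PSMA-p466") -> EpitopeProfile:
    """IFN-γ-dominant epitope: 60% responder probability, strong signal, no IL-10."""
    return EpitopeProfile(
        epitope_id=epitope_id,
        ifng=CytokineProfile(0.6, 40.0, 5.0),
        il10=CytokineProfile(0.0, 0.0, 5.0),
        intended_label=Label.TH1_SELECTIVE,
    )


def il10_only_profile(epitope_id: str = "MYC-p30") -> EpitopeProfile:
    """IL-10-dominant epitope: the mirror image of the strong Th1 profile."""
    return EpitopeProfile(
        epitope_id=epitope_id,
        ifng=CytokineProfile(0.0, 0.0, 5.0),
        il10=CytokineProfile(0.6, 40.0, 5.0),
        intended_label=Label.TH2_SELECTIVE,
    )


def null_profile(epitope_id: str = "HIV-p52") -> EpitopeProfile:
    """Non-reactive epitope: experimental and control wells share one mean."""
    return EpitopeProfile(
        epitope_id=epitope_id,
        ifng=CytokineProfile(0.0, 0.0, 5.0),
        il10=CytokineProfile(0.0, 0.0, 5.0),
        intended_label=Label.NON_REACTIVE,
    )


def mixed_profile(epitope_id: str = "AMACR-p200") -> EpitopeProfile:
    """Comparable IFN-γ and IL-10 responses: a mixed Th1/Th2 epitope."""
    both = CytokineProfile(0.5, 30.0, 5.0)
    return EpitopeProfile(epitope_id, ifng=both, il10=both,
                          intended_label=Label.MIXED)


def default_epitope_panel() -> list[EpitopeProfile]:
    return [
        strong_th1_profile("PSMA-p466"),
        strong_th1_profile("HPN-p393"),
        mixed_profile("AMACR-p200"),
        il10_only_profile("MYC-p30"),
        null_profile("HIV-p52"),
    ]


def calibrated_tumor_arms(
    n_mice: int = 15,
    noise_cv: float = 0.3,
    control_volume_day50: float = 1650.0,
    treated_volume_day50: float = 231.0,
    baseline_volume: float = 5.0,
) -> dict[str, tuple[int, GrowthModel]]:
    """Two-arm scenario whose expected mean volumes at day 50 match the given
    control/treated targets (default 1650 vs 231 mm³, an 86% inhibition)."""
    r = float(np.log(control_volume_day50 / baseline_volume) / 50.0)
    effect = float(np.log(treated_volume_day50 / baseline_volume)
                   / np.log(control_volume_day50 / baseline_volume))
    control = GrowthModel(baseline_volume=baseline_volume, growth_rate=r,
                          arm_effect=1.0, noise_cv=noise_cv)
    treated = GrowthModel(baseline_volume=baseline_volume, growth_rate=r,
                          arm_effect=effect, noise_cv=noise_cv)
    return {"adjuvant": (n_mice, control), "vaccine": (n_mice, treated)}
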