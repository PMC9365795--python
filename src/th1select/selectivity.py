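"""Th1/Th2 epitope selectivity classification.

A peptide epitope that drives IFN-γ secretion (Type I helper response) is a
vaccine candidate; one that mainly drives IL-10 (Type II / regulatory) can
abrogate anti-tumor immunity and must be edited out.  The discriminating
statistic is the ratio of the incidence × magnitude products from paired
IFN-γ and IL-10 ELISPOT cohort summaries:

    ratio = (IFN-γ incidence × IFN-γ magnitude) / (IL-10 incidence × IL-10 magnitude)

A ratio strictly greater than 4, with at most 10% of donors mounting an
IL-10 response, defines a Th1-selective epitope; a ratio strictly below 1
defines a Th2-selective epitope; anything between is a mixed response.  An
epitope with neither cytokine product positive is non-reactive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .elispot import Cytokine, EpitopeCohortSummary

__all__ = [
    "Label",
    "ClassifierConfig",
    "SelectivityCall",
    "selectivity_ratio",
    "classify",
    "classify_pair",
    "classify_panel",
    "calls_frame",
]

logger = logging.getLogger(__name__)


class Label(str, Enum):
    TH1_SELECTIVE = "TH1_SELECTIVE"
    TH2_SELECTIVE = "TH2_SELECTIVE"
    MIXED = "MIXED"
    NON_REACTIVE = "NON_REACTIVE"


@dataclass(frozen=True)
class ClassifierConfig:
    th1_ratio_threshold: float = 4.0
    th2_ratio_threshold: float = 1.0
    il10_incidence_cap: float = 10.0  # percent

    def __post_init__(self) -> None:
        if not self.th2_ratio_threshold < self.th1_ratio_threshold:
            raise ValueError("th2_ratio_threshold must be < th1_ratio_threshold")
        if not (0.0 <= self.il10_incidence_cap <= 100.0):
            raise ValueError("il10_incidence_cap must be in [0, 100]")


@dataclass(frozen=True)
class SelectivityCall:
    epitope_id: str
    ifng_incidence: float
    ifng_magnitude: float
    il10_incidence: float
    il10_magnitude: float
    ratio: float  # may be inf (no IL-10 product) or nan (non-reactive)
    label: Label


def selectivity_ratio(
    ifng: EpitopeCohortSummary, il10: EpitopeCohortSummary
) -> float:
    """Ratio of IFN-γ to IL-10 incidence × magnitude products.

    Returns ``inf`` when only the IFN-γ product is positive and ``nan`` when
    both products are zero (non-reactive epitope).  The units of incidence
    (percent vs fraction) cancel as long as both summaries use the same.
    """
    if ifng.epitope_id != il10.epitope_id:
        raise ValueError(
            f"epitope mismatch: {ifng.epitope_id!r} vs {il10.epitope_id!r}"
        )
    num = ifng.incidence * ifng.magnitude
    den = il10.incidence * il10.magnitude
    if den == 0.0:
        return math.inf if num > 0.0 else math.nan
    return num / den


def classify(
    ratio: float, il10_incidence: float, config: ClassifierConfig = ClassifierConfig()
) -> Label:
    """Map a selectivity ratio and IL-10 incidence (%) to a label.

    Boundaries follow the definition exactly: strictly > 4 (with IL-10
    incidence ≤ 10%, inclusive) for Th1-selective, strictly < 1 for
    Th2-selective, mixed otherwise; an undefined ratio (both products zero)
    is non-reactive.
    """
    if math.isnan(ratio):
        return Label.NON_REACTIVE
    if ratio > config.th1_ratio_threshold and il10_incidence <= config.il10_incidence_cap:
        return Label.TH1_SELECTIVE
    if ratio < config.th2_ratio_threshold:
        return Label.TH2_SELECTIVE
    return Label.MIXED


def classify_pair(
    ifng: EpitopeCohortSummary,
    il10: EpitopeCohortSummary,
    config: ClassifierConfig = ClassifierConfig(),
) -> SelectivityCall:
    ratio = selectivity_ratio(ifng, il10)
    return SelectivityCall(
        epitope_id=ifng.epitope_id,
        ifng_incidence=ifng.incidence,
        ifng_magnitude=ifng.magnitude,
        il10_incidence=il10.incidence,
        il10_magnitude=il10.magnitude,
        ratio=ratio,
        label=classify(ratio, il10.incidence, config),
    )


def classify_panel(
    summaries: Sequence[EpitopeCohortSummary],
    config: ClassifierConfig = ClassifierConfig(),
) -> list[SelectivityCall]:
    """Classify every epitope with both cytokine summaries, sorted by id.

    Epitopes lacking one of the two cytokines are skipped with a warning.
    """
    by_epitope: dict[str, dict[Cytokine, EpitopeCohortSummary]] = {}
    for s in summaries:
        by_epitope.setdefault(s.epitope_id, {})[s.cytokine] = s
    calls = []
    for epi in sorted(by_epitope):
        pair = by_epitope[epi]
        if Cytokine.IFNG not in pair or Cytokine.IL10 not in pair:
            logger.warning("epitope %s missing one cytokine summary; skipped", epi)
            continue
        calls.append(classify_pair(pair[Cytokine.IFNG], pair[Cytokine.IL10], config))
    if not calls:
        logger.warning("no paired epitopes in panel; empty classification")
    return calls


def calls_frame(calls: Sequence[SelectivityCall]) -> pd.DataFrame:
    """Tabulate calls; inf/nan ratios are spelled as the text tokens inf/nan."""
    def fmt_ratio(r: float) -> str:
        if math.isnan(r):
            return "nan"
        if math.isinf(r):
            return "inf"
        return repr(r)

    return pd.DataFrame({
        "epitope": [c.epitope_id for c in calls],
        "ifng_incidence": [c.ifng_incidence for c in calls],
        "ifng_magnitude": [c.ifng_magnitude for c in calls],
        "il10_incidence": [c.il10_incidence for c in calls],
        "il10_magnitude": [c.il10_magnitude for c in calls],
        "ratio": [fmt_ratio(c.ratio) for c in calls],
        "label": [c.label.value for c in calls],
    })
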