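"""ELISPOT spot-count statistics: corrected spots per well, response calls,
and donor-cohort summaries.

An ELISPOT assay counts cytokine-secreting cells as spots.  Each donor ×
epitope × cytokine unit consists of replicate antigen-stimulated wells and
replicate no-antigen control wells (nominally 4 each).  The magnitude of a
response is the corrected spots per well (CSPW): mean experimental spots
minus mean control spots.  A donor is called a positive responder when the
replicate counts differ significantly (two-tailed, unpaired) at p < 0.05 and
the CSPW is positive — more spots with antigen than without.

Cohort summaries reduce per-donor calls to the two quantities the selectivity
classifier consumes: incidence (percent of donors positive) and magnitude
(mean CSPW, by default over responders only).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Cytokine",
    "EpitopeAssay",
    "DonorResponse",
    "EpitopeCohortSummary",
    "cspw",
    "call_response",
    "summarize_cohort",
    "call_cohort",
    "cohort_summaries",
    "read_wells",
    "wells_to_assays",
    "responses_frame",
    "summaries_frame",
]

logger = logging.getLogger(__name__)


class Cytokine(str, Enum):
    IFNG = "IFNG"
    IL10 = "IL10"


@dataclass(frozen=True)
class EpitopeAssay:
    """Replicate wells for one donor × epitope × cytokine unit."""

    donor_id: str
    epitope_id: str
    cytokine: Cytokine
    experimental_wells: tuple[int, ...]
    control_wells: tuple[int, ...]
    cells_per_well: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cytokine", Cytokine(self.cytokine))
        for name in ("experimental_wells", "control_wells"):
            wells = tuple(getattr(self, name))
            object.__setattr__(self, name, wells)
            if len(wells) < 2:
                raise ValueError(
                    f"{self.donor_id}/{self.epitope_id}: insufficient replicates "
                    f"in {name} (need >= 2, got {len(wells)})"
                )
            for w in wells:
                if w < 0 or int(w) != w:
                    raise ValueError(
                        f"{self.donor_id}/{self.epitope_id}: spot counts must be "
                        f"non-negative integers, got {w!r}"
                    )


@dataclass(frozen=True)
class DonorResponse:
    donor_id: str
    epitope_id: str
    cytokine: Cytokine
    cspw: float
    p_value: float
    positive: bool


@dataclass(frozen=True)
class EpitopeCohortSummary:
    """Incidence (%) and magnitude (mean CSPW) for one epitope × cytokine."""

    epitope_id: str
    cytokine: Cytokine
    n_donors: int
    incidence: float
    magnitude: float
    responders: tuple[str, ...] = ()

    @property
    def product(self) -> float:
        """incidence × magnitude, the quantity entering the selectivity ratio."""
        return self.incidence * self.magnitude


def cspw(assay: EpitopeAssay) -> float:
    """Corrected spots per well: mean experimental minus mean control spots.

    May be negative; no clamping is applied.
    """
    return float(np.mean(assay.experimental_wells) - np.mean(assay.control_wells))


def _permutation_p(exp: Sequence[int], ctl: Sequence[int]) -> float:
    """Exhaustive two-sided permutation p-value on the absolute mean difference."""
    pooled = list(exp) + list(ctl)
    n_exp = len(exp)
    observed = abs(float(np.mean(exp)) - float(np.mean(ctl)))
    total = 0
    at_least = 0
    for idx in itertools.combinations(range(len(pooled)), n_exp):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        diff = abs(float(np.mean(grp)) - float(np.mean(rest)))
        total += 1
        if diff >= observed - 1e-12:
            at_least += 1
    return at_least / total


def call_response(
    assay: EpitopeAssay, alpha: float = 0.05, test: str = "student"
) -> DonorResponse:
    """Call one donor's response from the replicate spot counts.

    The p-value is from an unpaired two-tailed comparison of experimental
    versus control wells (``test``: "student" for the pooled-variance t —
    the default, well calibrated at 4 replicates — "welch" for the
    unequal-variance t, which is conservative at these group sizes, or
    "permutation" for the exhaustive relabeling test).
    Positive requires both p < alpha and CSPW > 0.  Integer counts make tied,
    zero-variance replicates possible: when the t statistic is degenerate the
    call falls back to the permutation test (p = 1 when all wells are equal).
    """
    exp = assay.experimental_wells
    ctl = assay.control_wells
    value = cspw(assay)

    exp_var = float(np.var(exp, ddof=1))
    ctl_var = float(np.var(ctl, ddof=1))

    if test == "permutation":
        p = _permutation_p(exp, ctl)
    elif exp_var == 0.0 and ctl_var == 0.0:
        p = 1.0 if value == 0.0 else _permutation_p(exp, ctl)
    else:
        # near-identical replicate groups trip scipy's precision-loss warning;
        # the degenerate outcomes are handled via the permutation fallback
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if test == "welch":
                res = stats.ttest_ind(exp, ctl, equal_var=False)
            elif test == "student":
                res = stats.ttest_ind(exp, ctl, equal_var=True)
            else:
                raise ValueError(f"unknown test: {test!r}")
        p = float(res.pvalue)
        if math.isnan(p):
            p = _permutation_p(exp, ctl)

    return DonorResponse(
        donor_id=assay.donor_id,
        epitope_id=assay.epitope_id,
        cytokine=assay.cytokine,
        cspw=value,
        p_value=p,
        positive=bool(p < alpha and value > 0),
    )


def summarize_cohort(
    responses: Sequence[DonorResponse],
    epitope_id: Optional[str] = None,
    cytokine: Optional[Cytokine] = None,
    magnitude_over: str = "responders",
) -> EpitopeCohortSummary:
    """Reduce per-donor calls to cohort incidence and magnitude.

    incidence = 100 × (#positive / n_donors).  magnitude defaults to the mean
    CSPW over positive responders (0 when none respond); with
    ``magnitude_over="all"`` it averages CSPW over every evaluable donor,
    which dilutes magnitude toward zero as incidence falls.
    """
    if not responses:
        raise ValueError("empty cohort: no donor responses")
    if epitope_id is None:
        epitope_id = responses[0].epitope_id
    if cytokine is None:
        cytokine = responses[0].cytokine
    cytokine = Cytokine(cytokine)
    seen: set[str] = set()
    for r in responses:
        if r.epitope_id != epitope_id or r.cytokine != cytokine:
            raise ValueError(
                f"response for {r.epitope_id}/{r.cytokine} mixed into cohort "
                f"{epitope_id}/{cytokine}"
            )
        if r.donor_id in seen:
            raise ValueError(f"duplicate donor in cohort: {r.donor_id}")
        seen.add(r.donor_id)

    n = len(responses)
    positives = [r for r in responses if r.positive]
    incidence = 100.0 * len(positives) / n
    if magnitude_over == "responders":
        magnitude = float(np.mean([r.cspw for r in positives])) if positives else 0.0
    elif magnitude_over == "all":
        magnitude = float(np.mean([r.cspw for r in responses]))
    else:
        raise ValueError(f"magnitude_over must be 'responders' or 'all', got {magnitude_over!r}")
    return EpitopeCohortSummary(
        epitope_id=epitope_id,
        cytokine=cytokine,
        n_donors=n,
        incidence=incidence,
        magnitude=magnitude,
        responders=tuple(sorted(r.donor_id for r in positives)),
    )


def call_cohort(
    assays: Iterable[EpitopeAssay], alpha: float = 0.05, test: str = "student"
) -> list[DonorResponse]:
    """Call every assay in a cohort."""
    return [call_response(a, alpha=alpha, test=test) for a in assays]


def cohort_summaries(
    responses: Sequence[DonorResponse],
    magnitude_over: str = "responders",
    require_both_cytokines: bool = True,
) -> list[EpitopeCohortSummary]:
    """Summarize a panel of per-donor calls into per-epitope × cytokine rows.

    Donors missing either cytokine for an epitope are excluded pairwise from
    that epitope's summaries (and logged), so the incidence denominators of
    the two cytokines agree.
    """
    by_key: dict[tuple[str, Cytokine], dict[str, DonorResponse]] = {}
    for r in responses:
        by_key.setdefault((r.epitope_id, r.cytokine), {})
        if r.donor_id in by_key[(r.epitope_id, r.cytokine)]:
            raise ValueError(
                f"duplicate donor {r.donor_id} for {r.epitope_id}/{r.cytokine}"
            )
        by_key[(r.epitope_id, r.cytokine)][r.donor_id] = r

    epitopes = sorted({k[0] for k in by_key})
    out: list[EpitopeCohortSummary] = []
    for epi in epitopes:
        groups = {c: by_key.get((epi, c), {}) for c in Cytokine}
        present = [c for c in Cytokine if groups[c]]
        if require_both_cytokines and len(present) == 2:
            donors = set(groups[Cytokine.IFNG]) & set(groups[Cytokine.IL10])
            dropped = (set(groups[Cytokine.IFNG]) | set(groups[Cytokine.IL10])) - donors
            if dropped:
                logger.warning(
                    "epitope %s: excluding donors missing one cytokine: %s",
                    epi, sorted(dropped),
                )
        else:
            donors = set().union(*(set(groups[c]) for c in present))
        for c in present:
            subset = [groups[c][d] for d in sorted(donors) if d in groups[c]]
            if subset:
                out.append(summarize_cohort(subset, epi, c, magnitude_over))
    return out


WELL_COLUMNS = ["donor", "epitope", "cytokine", "well_type", "replicate",
                "spots", "cells_per_well"]


def wells_to_assays(df: pd.DataFrame) -> list[EpitopeAssay]:
    """Group a well-level table (one row per well) into EpitopeAssay units."""
    missing = [c for c in WELL_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")
    assays = []
    keys = ["donor", "epitope", "cytokine"]
    for (donor, epi, cyt), grp in df.groupby(keys, sort=True):
        exp = grp.loc[grp["well_type"] == "experimental", "spots"]
        ctl = grp.loc[grp["well_type"] == "control", "spots"]
        cells = None
        if "cells_per_well" in grp.columns and grp["cells_per_well"].notna().any():
            cells = int(grp["cells_per_well"].dropna().iloc[0])
        assays.append(EpitopeAssay(
            donor_id=str(donor),
            epitope_id=str(epi),
            cytokine=Cytokine(str(cyt)),
            experimental_wells=tuple(int(s) for s in exp),
            control_wells=tuple(int(s) for s in ctl),
            cells_per_well=cells,
        ))
    return assays


def read_wells(path) -> list[EpitopeAssay]:
    """Read a well-level CSV (``donor,epitope,cytokine,well_type,replicate,spots,cells_per_well``)."""
    return wells_to_assays(pd.read_csv(path))


def responses_frame(responses: Sequence[DonorResponse]) -> pd.DataFrame:
    return pd.DataFrame({
        "donor": [r.donor_id for r in responses],
        "epitope": [r.epitope_id for r in responses],
        "cytokine": [r.cytokine.value for r in responses],
        "cspw": [r.cspw for r in responses],
        "p_value": [r.p_value for r in responses],
        "positive": [r.positive for r in responses],
    })


def summaries_frame(summaries: Sequence[EpitopeCohortSummary]) -> pd.DataFrame:
    return pd.DataFrame({
        "epitope": [s.epitope_id for s in summaries],
        "cytokine": [s.cytokine.value for s in summaries],
        "n_donors": [s.n_donors for s in summaries],
        "incidence_pct": [s.incidence for s in summaries],
        "magnitude_cspw": [s.magnitude for s in summaries],
    })
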