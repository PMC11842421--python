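"""Smoking-exposure classification from newborn-blood biomarkers plus the
birth-record report, and cohort summary bookkeeping.

A mother is classified as a smoker if any of three indicators fires:

* self/provider-reported smoker on the birth record;
* cotinine detected in the newborn blood spot (the biomarker feature is
  non-absent after replicate summarization);
* hydroxycotinine intensity in the top fraction (default 14%) of all
  samples, non-detects participating in the ranking as 0.

The top-fraction cutoff is a quantile over ALL samples with absent -> 0;
ties at the cutoff are all included, and a non-detected sample can never
be flagged by the hydroxycotinine rule (a cutoff of 0 would otherwise
flag everyone when fewer than the top fraction are detected).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    AGE_LEVELS,
    BIRTH_YEAR_LEVELS,
    RACE_LEVELS,
    SES_LEVELS,
    SEX_LEVELS,
    FeatureTable,
    SampleRecord,
)
from .qc import summarize_replicates

__all__ = [
    "ExposureRule",
    "BiomarkerVector",
    "ExposureCall",
    "CohortSummary",
    "extract_biomarker",
    "classify",
    "classify_from_table",
    "cohort_summary",
    "round_half_up",
]

COTININE_MZ = 177.1023
HYDROXYCOTININE_MZ = 193.0973


@dataclass(frozen=True)
class ExposureRule:
    cotinine_mz: float = COTININE_MZ
    hydroxycotinine_mz: float = HYDROXYCOTININE_MZ
    mz_tol_ppm: float = 5.0
    hydroxycotinine_top_frac: float = 0.14

    def __post_init__(self) -> None:
        if not (0 < self.hydroxycotinine_top_frac < 1):
            raise ValueError("hydroxycotinine_top_frac must be in (0, 1)")
        if self.mz_tol_ppm <= 0:
            raise ValueError("mz_tol_ppm must be positive")


@dataclass
class BiomarkerVector:
    """Per-sample summarized intensity of one biomarker; NaN = not detected.

    ``feature_id`` is None when no feature fell within tolerance of the
    target m/z ("biomarker absent from table": every sample non-detected).
    """

    values: pd.Series
    feature_id: str | None
    target_mz: float

    @property
    def absent_from_table(self) -> bool:
        return self.feature_id is None


@dataclass(frozen=True)
class ExposureCall:
    sample_id: str
    smoker: bool
    triggered_by: frozenset[str]  # subset of {report, cotinine, hydroxycotinine}

    def __post_init__(self) -> None:
        if self.smoker != bool(self.triggered_by):
            raise ValueError("smoker flag must match non-empty triggered_by")


def extract_biomarker(
    summarized: pd.DataFrame,
    mz: np.ndarray,
    target_mz: float,
    tol_ppm: float = 5.0,
) -> BiomarkerVector:
    """Select the feature nearest ``target_mz`` within ``tol_ppm`` and return
    its per-sample summarized intensities (pre-auto-scaling).

    ``summarized`` is the feature x sample matrix from
    :func:`mwaskit.qc.summarize_replicates`; ``mz`` aligns with its rows.
    """
    mz = np.asarray(mz, dtype=float)
    if len(mz) != len(summarized.index):
        raise ValueError("mz vector does not align with the summarized matrix rows")
    if len(mz) == 0:
        return BiomarkerVector(
            values=pd.Series(np.nan, index=summarized.columns, dtype=float),
            feature_id=None,
            target_mz=target_mz,
        )
    ppm = 1e6 * np.abs(mz - target_mz) / target_mz
    best = int(np.argmin(ppm))
    if ppm[best] > tol_ppm:
        return BiomarkerVector(
            values=pd.Series(np.nan, index=summarized.columns, dtype=float),
            feature_id=None,
            target_mz=target_mz,
        )
    return BiomarkerVector(
        values=summarized.iloc[best].astype(float),
        feature_id=str(summarized.index[best]),
        target_mz=target_mz,
    )


def top_fraction_cutoff(values: np.ndarray, top_frac: float) -> float:
    """Cutoff such that values >= cutoff form (about) the top fraction.

    Quantile with the 'higher' interpolation so that for n distinct values
    exactly ``floor-ish`` top_frac*n values sit at or above the cutoff
    (e.g. ranks 1..100, top_frac 0.14 -> cutoff 87 -> 14 flagged).
    """
    return float(np.quantile(np.asarray(values, dtype=float), 1.0 - top_frac, method="higher"))


def classify(
    samples: Sequence[SampleRecord],
    cotinine: BiomarkerVector,
    hydroxycotinine: BiomarkerVector,
    rule: ExposureRule = ExposureRule(),
) -> list[ExposureCall]:
    """Apply the union rule; ``triggered_by`` records every satisfied indicator."""
    ids = [s.sample_id for s in samples]
    cot = cotinine.values.reindex(ids)
    hyd = hydroxycotinine.values.reindex(ids).fillna(0.0).to_numpy()
    cutoff = top_fraction_cutoff(hyd, rule.hydroxycotinine_top_frac)

    calls: list[ExposureCall] = []
    for i, rec in enumerate(samples):
        triggers = set()
        if rec.reported_smoker:
            triggers.add("report")
        if not np.isnan(cot.iloc[i]):
            triggers.add("cotinine")
        if hyd[i] >= cutoff and hyd[i] > 0:
            triggers.add("hydroxycotinine")
        calls.append(
            ExposureCall(
                sample_id=rec.sample_id,
                smoker=bool(triggers),
                triggered_by=frozenset(triggers),
            )
        )
    return calls


def classify_from_table(
    table: FeatureTable,
    samples: Sequence[SampleRecord],
    rule: ExposureRule = ExposureRule(),
) -> list[ExposureCall]:
    """Convenience wrapper: summarize replicates, extract both biomarkers from
    the raw (pre-QC) table and classify."""
    summarized = summarize_replicates(table)
    cot = extract_biomarker(summarized, table.mz, rule.cotinine_mz, rule.mz_tol_ppm)
    hyd = extract_biomarker(summarized, table.mz, rule.hydroxycotinine_mz, rule.mz_tol_ppm)
    return classify(samples, cot, hyd, rule)


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_INDICATOR_PRIORITY = ("report", "cotinine", "hydroxycotinine")

_COVARIATE_LEVELS: dict[str, tuple] = {
    "race_ethnicity": RACE_LEVELS,
    "maternal_age": AGE_LEVELS,
    "birth_year_band": BIRTH_YEAR_LEVELS,
    "sex": SEX_LEVELS,
    "ses": SES_LEVELS,
}


@dataclass
class CohortSummary:
    n_samples: int
    n_smokers: int
    prevalence_pct: int  # rounded to nearest integer percent
    # indicator -> (count, % of all samples to 1 decimal); overlapping counts
    indicators: dict[str, tuple[int, float]]
    # same, but each smoker attributed to a single indicator by priority
    indicators_exclusive: dict[str, tuple[int, float]]
    # covariate -> level -> group -> (count, column % within group to 1 decimal)
    strata: dict[str, dict[object, dict[str, tuple[int, float]]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cov, levels in self.strata.items():
            for level, groups in levels.items():
                rows.append(
                    {
                        "covariate": cov,
                        "level": level,
                        "smoker_n": groups["smoker"][0],
                        "smoker_pct": groups["smoker"][1],
                        "nonsmoker_n": groups["nonsmoker"][0],
                        "nonsmoker_pct": groups["nonsmoker"][1],
                    }
                )
        return pd.DataFrame(rows)


def cohort_summary(
    calls: Sequence[ExposureCall], samples: Sequence[SampleRecord]
) -> CohortSummary:
    """Counts and percentages: overall prevalence (integer %), per-indicator
    shares of all samples (1 decimal), and within-group column percentages of
    each covariate level (1 decimal)."""
    if len(calls) == 0:
        raise ValueError("cohort summary of zero samples")
    if [c.sample_id for c in calls] != [s.sample_id for s in samples]:
        raise ValueError("calls are not aligned to samples")

    n = len(calls)
    smokers = [c.smoker for c in calls]
    n_smokers = int(sum(smokers))
    prevalence = int(round_half_up(100.0 * n_smokers / n, 0))

    indicators: dict[str, tuple[int, float]] = {}
    exclusive: dict[str, tuple[int, float]] = {}
    for ind in _INDICATOR_PRIORITY:
        cnt = sum(1 for c in calls if ind in c.triggered_by)
        indicators[ind] = (cnt, round_half_up(100.0 * cnt / n, 1))
    for ind in _INDICATOR_PRIORITY:
        pri = _INDICATOR_PRIORITY[: _INDICATOR_PRIORITY.index(ind)]
        cnt = sum(
            1
            for c in calls
            if ind in c.triggered_by and not any(p in c.triggered_by for p in pri)
        )
        exclusive[ind] = (cnt, round_half_up(100.0 * cnt / n, 1))

    strata: dict[str, dict[object, dict[str, tuple[int, float]]]] = {}
    group_totals = {"smoker": n_smokers, "nonsmoker": n - n_smokers}
    for cov, levels in _COVARIATE_LEVELS.items():
        strata[cov] = {}
        for level in levels:
            entry: dict[str, tuple[int, float]] = {}
            for group, is_smoker in (("smoker", True), ("nonsmoker", False)):
                cnt = sum(
                    1
                    for c, s in zip(calls, samples)
                    if c.smoker == is_smoker and getattr(s, cov) == level
                )
                tot = group_totals[group]
                pct = round_half_up(100.0 * cnt / tot, 1) if tot else float("nan")
                entry[group] = (cnt, pct)
            strata[cov][level] = entry
    return CohortSummary(
        n_samples=n,
        n_smokers=n_smokers,
        prevalence_pct=prevalence,
        indicators=indicators,
        indicators_exclusive=exclusive,
        strata=strata,
    )
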