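"""Univariate logistic regression of tumor-event occurrence on exposure factors.

Each model regresses the binary tumor-event indicator on one categorical
exposure (age band, sex, drug group, or daily-dose band), reporting per-level
odds ratios ``Exp(Beta)`` with Wald 95% confidence intervals and p-values
against the reference level.  For a binary exposure the fit is saturated, so
``Exp(Beta)`` equals the sample odds ratio ``(a*d)/(b*c)`` exactly — the same
quantity the disproportionality scan estimates — which links the two modules
as mutual oracles.

Band conventions (boundaries assigned inclusively to the middle band):

* age: ``<65`` (reference), ``65-75`` (both endpoints included), ``>75``;
* daily dose: Low ``<=20`` mg/day (reference), Medium ``(20, 40]``, High
  ``>40``.

Cases missing the exposure are excluded from that model and counted; levels
with a zero cell (no events or no non-events) are flagged non-estimable and
dropped from the design rather than crashing the fit.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import STUDY_PPIS
from .meddra import TAEClassification
from .signals import Z_95

logger = logging.getLogger(__name__)

AGE_BANDS = ("<65", "65-75", ">75")
DOSE_BANDS = ("Low", "Medium", "High")


class SingleClassError(ValueError):
    """The outcome has only one class; a logistic model is not identifiable."""


def band_age(age: float | None) -> str | None:
    """Age band: <65 / 65-75 (inclusive) / >75; missing stays missing."""
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return None
    if age < 65:
        return AGE_BANDS[0]
    if age <= 75:
        return AGE_BANDS[1]
    return AGE_BANDS[2]


def band_dose(daily_dose: float | None) -> str | None:
    """Dose band: Low <=20 / Medium (20, 40] / High >40 mg/day."""
    if daily_dose is None or (isinstance(daily_dose, float) and math.isnan(daily_dose)):
        return None
    if daily_dose <= 20:
        return DOSE_BANDS[0]
    if daily_dose <= 40:
        return DOSE_BANDS[1]
    return DOSE_BANDS[2]


@dataclass(frozen=True)
class ExposureSpec:
    """One categorical exposure with its ordered levels, reference first."""

    variable: str
    levels: tuple[str, ...]

    @property
    def reference(self) -> str:
        return self.levels[0]


AGE_SPEC = ExposureSpec("age_band", AGE_BANDS)
SEX_SPEC = ExposureSpec("sex", ("female", "male"))
GROUP_SPEC = ExposureSpec("group", tuple(sorted(STUDY_PPIS)))
DOSE_SPEC = ExposureSpec("dose_band", DOSE_BANDS)


@dataclass
class LogisticFit:
    """Per-level odds ratios from one univariate logistic model."""

    variable: str
    reference: str
    table: pd.DataFrame  # level, n, n_events, odds_ratio, ci_low, ci_high, p, estimable
    n_used: int
    n_excluded_missing: int
    converged: bool
    n_iterations: int
    log_likelihood: float
    null_log_likelihood: float
    subgroup: str = "All"

    def level_row(self, level: str) -> pd.Series:
        return self.table.set_index("level").loc[level]


def build_model_frame(
    cases: Sequence,
    classification: TAEClassification,
    study_drugs: Sequence[str] = STUDY_PPIS,
) -> pd.DataFrame:
    """Case-level modelling frame: outcome flag plus banded exposures."""
    from .ingest import cases_to_frame  # local import to avoid cycle

    frame = cases_to_frame(cases, study_drugs)
    frame["is_tae"] = list(classification.is_tae)
    frame["age_band"] = [band_age(a) for a in frame["age"]]
    frame["dose_band"] = [band_dose(d) for d in frame["dose_mg_day"]]
    frame.loc[~frame["sex"].isin(("female", "male")), "sex"] = None
    return frame


def fit_univariate(
    frame: pd.DataFrame,
    spec: ExposureSpec,
    outcome: str = "is_tae",
    weight_col: str | None = None,
    z: float = Z_95,
    subgroup: str = "All",
) -> LogisticFit:
    """Maximum-likelihood logistic fit of the outcome on one exposure.

    ``frame`` needs the outcome column and ``spec.variable``; rows with a
    missing exposure (or a level outside ``spec.levels``) are excluded and
    counted.  ``weight_col`` allows pre-aggregated data via frequency
    weights.
    """
    df = frame[frame[spec.variable].isin(spec.levels)].copy()
    n_excluded = len(frame) - len(df)
    w = df[weight_col].to_numpy(float) if weight_col else np.ones(len(df))
    y = df[outcome].astype(float).to_numpy()
    if len(df) == 0 or (y * w).sum() == 0 or ((1 - y) * w).sum() == 0:
        raise SingleClassError(
            f"outcome {outcome!r} needs both classes to fit {spec.variable!r}"
        )

    # Estimability per level: both an event and a non-event cell.
    cells = {}
    for level in spec.levels:
        mask = (df[spec.variable] == level).to_numpy()
        cells[level] = ((y * w)[mask].sum(), ((1 - y) * w)[mask].sum())
    if min(cells[spec.reference]) == 0:
        raise SingleClassError(
            f"reference level {spec.reference!r} has a zero cell; "
            "odds ratios against it are not estimable"
        )
    estimable = {
        level: min(cells[level]) > 0 and cells[level][0] + cells[level][1] > 0
        for level in spec.levels
    }
    fit_levels = [
        level
        for level in spec.levels[1:]
        if estimable[level] and cells[level][0] + cells[level][1] > 0
    ]
    for level in spec.levels[1:]:
        if not estimable[level] and cells[level][0] + cells[level][1] > 0:
            logger.warning(
                "%s level %r has a zero cell (complete separation); "
                "flagged non-estimable",
                spec.variable,
                level,
            )

    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for level in fit_levels:
        X[level] = (df[spec.variable] == level).astype(float)
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    res = model.fit(maxiter=100, tol=1e-10)
    null_model = sm.GLM(
        y, np.ones((len(df), 1)), family=sm.families.Binomial(), freq_weights=w
    )
    null_res = null_model.fit()

    rows = []
    for level in spec.levels:
        n_level = int(round(sum(cells[level])))
        n_events = int(round(cells[level][0]))
        if level == spec.reference:
            rows.append(
                {
                    "level": level,
                    "n": n_level,
                    "n_events": n_events,
                    "odds_ratio": math.nan,
                    "ci_low": math.nan,
                    "ci_high": math.nan,
                    "p_value": math.nan,
                    "estimable": True,
                    "reference": True,
                }
            )
            continue
        if level in fit_levels:
            beta = float(res.params[level])
            se = float(res.bse[level])
            rows.append(
                {
                    "level": level,
                    "n": n_level,
                    "n_events": n_events,
                    "odds_ratio": math.exp(beta),
                    "ci_low": math.exp(beta - z * se),
                    "ci_high": math.exp(beta + z * se),
                    "p_value": float(res.pvalues[level]),
                    "estimable": True,
                    "reference": False,
                }
            )
        else:
            rows.append(
                {
                    "level": level,
                    "n": n_level,
                    "n_events": n_events,
                    "odds_ratio": math.nan,
                    "ci_low": math.nan,
                    "ci_high": math.nan,
                    "p_value": math.nan,
                    "estimable": False,
                    "reference": False,
                }
            )
    return LogisticFit(
        variable=spec.variable,
        reference=spec.reference,
        table=pd.DataFrame(rows),
        n_used=int(round(w.sum())),
        n_excluded_missing=n_excluded,
        converged=bool(res.converged),
        n_iterations=len(res.fit_history["deviance"]) - 1,
        log_likelihood=float(res.llf),
        null_log_likelihood=float(null_res.llf),
        subgroup=subgroup,
    )


def standard_fits(frame: pd.DataFrame) -> dict[str, LogisticFit]:
    """The study's exposure models: age band, sex and drug group."""
    out = {}
    for spec in (AGE_SPEC, SEX_SPEC, GROUP_SPEC):
        try:
            out[spec.variable] = fit_univariate(frame, spec)
        except SingleClassError as err:
            logger.warning("skipping %s: %s", spec.variable, err)
    return out


def dose_subgroups(
    frame: pd.DataFrame,
    study_drugs: Sequence[str] = STUDY_PPIS,
    per_drug: bool = True,
) -> list[LogisticFit]:
    """Dose-band models: one pooled fit over all study-drug cases plus one per
    drug, with the Low band as reference.

    Drugs with fewer than two populated dose bands are skipped with a warning.
    """
    fits: list[LogisticFit] = []
    pooled = frame[frame["group"].notna()]

    def try_fit(sub: pd.DataFrame, label: str) -> None:
        populated = sub.loc[sub["dose_band"].notna(), "dose_band"].nunique()
        if populated < 2:
            logger.warning(
                "dose model for %s skipped: only %d populated band(s)",
                label,
                populated,
            )
            return
        try:
            fits.append(fit_univariate(sub, DOSE_SPEC, subgroup=label))
        except SingleClassError as err:
            logger.warning("dose model for %s skipped: %s", label, err)

    try_fit(pooled, "All")
    if per_drug:
        for drug in study_drugs:
            try_fit(pooled[pooled["group"] == drug], drug)
    return fits


def fits_frame(fits: Sequence[LogisticFit]) -> pd.DataFrame:
    """Flatten fits into one table mirroring the study's risk-factor layout."""
    rows = []
    for fit in fits:
        for row in fit.table.to_dict("records"):
            rows.append(
                {
                    "subgroup": fit.subgroup,
                    "variable": fit.variable,
                    **row,
                    "n_model": fit.n_used,
                }
            )
    return pd.DataFrame(rows)
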