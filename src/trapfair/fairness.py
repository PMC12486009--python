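"""Fairness audit: are exposure-assessment errors associated with demographics?

The exposure-assessment error ("parcel-based bias") of a candidate measure in
a unit is its decile minus the parcel-proximity reference decile, an integer
in [-9, 9].  Errors are regressed (OLS with intercept, classical homoskedastic
95% CI) on each demographic covariate — fraction non-Hispanic Black and the
material deprivation index — and also summarized by Kendall's tau-b.  A
measure is unfair with respect to a covariate when its error is statistically
associated with it (CI excluding zero).

Covariates are z-scored before fitting by default, so slopes are decile-error
per standard deviation of covariate and comparable across covariates; raw
scale is available via ``standardize=False``.  Errors are kept on the decile
scale — the only scale on which the three measures are commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .agreement import CANDIDATE_MEASURES, kendall_tau
from .types import DemographicRecord, InputError

__all__ = [
    "exposure_errors",
    "fairness_regression",
    "fairness_tau",
    "assess_fairness",
    "FairnessResult",
    "RegressionFit",
    "ERROR_COLUMNS",
    "COVARIATES",
]

ERROR_COLUMNS = [
    "level", "unit_id", "error_ej", "error_density",
    "fraction_nh_black", "deprivation_index",
]

#: Covariates the audit regresses errors on.
COVARIATES = ("deprivation_index", "fraction_nh_black")

_MEASURE_TO_ERROR = {"ej_screen": "error_ej", "aadt_density": "error_density"}


class RegressionFit(NamedTuple):
    slope: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class FairnessResult:
    level: str
    measure: str
    covariate: str
    slope: float
    ci_low: float
    ci_high: float
    tau: float
    n_units: int
    significant: bool


def _demographics_frame(
    demographics: Union[pd.DataFrame, Iterable[DemographicRecord]]
) -> pd.DataFrame:
    if isinstance(demographics, pd.DataFrame):
        df = demographics
    else:
        df = pd.DataFrame(
            {
                "unit_id": r.unit_id,
                "level": r.level.value if hasattr(r.level, "value") else r.level,
                "fraction_nh_black": r.fraction_nh_black,
                "deprivation_index": r.deprivation_index,
            }
            for r in demographics
        )
    missing = {"unit_id", "fraction_nh_black", "deprivation_index"} - set(df.columns)
    if missing:
        raise InputError(f"demographics missing columns: {sorted(missing)}")
    return df


def exposure_errors(
    deciles: pd.DataFrame,
    demographics: Union[pd.DataFrame, Iterable[DemographicRecord]],
) -> pd.DataFrame:
    """Join decile errors (candidate minus parcel reference) with covariates.

    Every unit in the decile table must have a demographic record at the same
    level; a missing unit raises :class:`~trapfair.types.InputError` naming it.
    """
    demo = _demographics_frame(demographics)
    levels = deciles["level"].unique()
    if len(levels) != 1:
        raise InputError(f"decile table mixes levels: {sorted(levels)}")
    level = str(levels[0])
    if "level" in demo.columns:
        demo = demo[demo["level"] == level]
    demo = demo.set_index("unit_id")
    missing = [u for u in deciles["unit_id"] if u not in demo.index]
    if missing:
        raise InputError(
            f"missing demographic record(s) at level {level}: {missing[:5]}"
        )
    cov = demo.loc[deciles["unit_id"]]
    out = pd.DataFrame({
        "level": deciles["level"].to_numpy(),
        "unit_id": deciles["unit_id"].to_numpy(),
        "error_ej": (deciles["decile_ej"] - deciles["decile_parcel"]).to_numpy(),
        "error_density": (deciles["decile_density"] - deciles["decile_parcel"]).to_numpy(),
        "fraction_nh_black": cov["fraction_nh_black"].to_numpy(),
        "deprivation_index": cov["deprivation_index"].to_numpy(),
    })
    return out.sort_values("unit_id", ignore_index=True)


def fairness_regression(errors: Sequence[float], covariate: Sequence[float],
                        standardize: bool = True) -> RegressionFit:
    """OLS of error on covariate with intercept; 95% homoskedastic CI.

    With ``standardize=True`` (default) the covariate is z-scored first, so
    the slope is decile-error per covariate standard deviation.
    """
    y = np.asarray(errors, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise InputError("errors and covariate must be equal-length vectors")
    n = y.size
    if n < 3:
        raise InputError("fairness_regression: need n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise InputError("fairness_regression: covariate has zero variance")
    if standardize:
        x = (x - x.mean()) / sd
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = fit.conf_int(alpha=0.05)[1]
    return RegressionFit(float(fit.params[1]), float(lo), float(hi), n)


def fairness_tau(errors: Sequence[float], covariate: Sequence[float]) -> float:
    """Kendall's tau-b between errors and a covariate (same contract as
    :func:`trapfair.agreement.kendall_tau`)."""
    return kendall_tau(errors, covariate)


def assess_fairness(error_table: pd.DataFrame,
                    standardize: bool = True) -> List[FairnessResult]:
    """One regression + tau per (candidate measure x covariate).

    Returns 4 results per level (2 measures x 2 covariates); ``significant``
    means the 95% CI excludes zero.
    """
    missing = set(ERROR_COLUMNS) - set(error_table.columns)
    if missing:
        raise InputError(f"error table missing columns: {sorted(missing)}")
    levels = error_table["level"].unique()
    if len(levels) != 1:
        raise InputError(f"error table mixes levels: {sorted(levels)}")
    level = str(levels[0])
    results = []
    for measure in CANDIDATE_MEASURES:
        err = error_table[_MEASURE_TO_ERROR[measure]].to_numpy(dtype=float)
        for covariate in COVARIATES:
            cov = error_table[covariate].to_numpy(dtype=float)
            fit = fairness_regression(err, cov, standardize=standardize)
            tau = fairness_tau(err, cov)
            results.append(
                FairnessResult(
                    level=level,
                    measure=measure,
                    covariate=covariate,
                    slope=fit.slope,
                    ci_low=fit.ci_low,
                    ci_high=fit.ci_high,
                    tau=tau,
                    n_units=fit.n,
                    significant=not (fit.ci_low <= 0.0 <= fit.ci_high),
                )
            )
    return results
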