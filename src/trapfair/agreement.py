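"""Decile transformation and agreement statistics.

Exposure values are compared on the decile scale: within one geographic
level, each measure's values are ranked (average ranks for ties) and mapped
to 10 equal-count bins.  Rank-based deciles are invariant to any strictly
increasing transform of the raw values and reproducible under ties, which
value-quantile cuts are not.

Agreement between a candidate measure (EJScreen proximity or AADT density)
and the parcel-proximity reference is summarized three ways: the fraction of
units whose deciles differ by at most one ("good agreement"), unweighted
Cohen's kappa (chance-corrected exact match), and Kendall's tau-b (rank
correlation with tie correction — decile vectors are heavily tied, so the
tie-corrected variant is the appropriate one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import InputError

__all__ = [
    "to_deciles",
    "good_agreement",
    "cohens_kappa",
    "kendall_tau",
    "decile_table",
    "assess_agreement",
    "AgreementResult",
    "DECILE_COLUMNS",
    "CANDIDATE_MEASURES",
]

DECILE_COLUMNS = ["level", "unit_id", "decile_ej", "decile_density", "decile_parcel"]

#: Candidate measures compared against the parcel-proximity reference.
CANDIDATE_MEASURES = ("ej_screen", "aadt_density")

_MEASURE_TO_DECILE = {"ej_screen": "decile_ej", "aadt_density": "decile_density"}


@dataclass(frozen=True)
class AgreementResult:
    level: str
    measure: str
    good_agreement_fraction: float
    kappa: float
    tau: float
    n_units: int


def to_deciles(values: Sequence[float]) -> np.ndarray:
    """Map values to decile bins 1..10 by average rank then ceiling.

    decile(v) = ceil(10 * rank(v) / n) with ties sharing the mean rank.
    Monotone (v_i < v_j implies decile_i <= decile_j) and invariant to
    strictly increasing transforms of the input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("to_deciles: empty vector")
    if not np.all(np.isfinite(arr)):
        raise InputError("to_deciles: non-finite value in input")
    ranks = stats.rankdata(arr, method="average")
    return np.ceil(10.0 * ranks / arr.size).astype(int)


def _paired(a: Sequence[float], b: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError(f"length mismatch: {a.shape} vs {b.shape}")
    return a, b


def good_agreement(deciles_a: Sequence[int], deciles_b: Sequence[int]) -> float:
    """Fraction of units whose two decile assignments differ by at most one."""
    a, b = _paired(deciles_a, deciles_b)
    if a.size == 0:
        raise InputError("good_agreement: empty vectors")
    return float(np.mean(np.abs(a - b) <= 1))


def cohens_kappa(deciles_a: Sequence[int], deciles_b: Sequence[int]) -> float:
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e).

    p_o is the exact-match fraction; p_e the chance agreement from the two
    raters' marginal category frequencies.  When both raters are constant and
    identical (p_e = 1) kappa is defined as 1.
    """
    a, b = _paired(deciles_a, deciles_b)
    if a.size == 0:
        raise InputError("cohens_kappa: empty vectors")
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    p_a = np.array([np.mean(a == c) for c in cats])
    p_b = np.array([np.mean(b == c) for c in cats])
    p_e = float(p_a @ p_b)
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def kendall_tau(deciles_a: Sequence[float], deciles_b: Sequence[float]) -> float:
    """Kendall's tau-b (tie-corrected) rank correlation.

    Returns NaN with a warning when either vector is fully tied (the tau-b
    denominator vanishes).
    """
    a, b = _paired(deciles_a, deciles_b)
    if a.size < 2:
        raise InputError("kendall_tau: need at least 2 observations")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn(
            "kendall_tau: a fully tied vector makes tau-b undefined; returning NaN",
            UserWarning,
            stacklevel=2,
        )
        return float("nan")
    res = stats.kendalltau(a, b, variant="b")
    return float(res.statistic)


def decile_table(exposure_table: pd.DataFrame) -> pd.DataFrame:
    """Transform an exposure table's three measure columns to within-level deciles."""
    required = {"level", "unit_id", "ej_screen", "aadt_density", "parcel_proximity"}
    missing = required - set(exposure_table.columns)
    if missing:
        raise InputError(f"exposure table missing columns: {sorted(missing)}")
    levels = exposure_table["level"].unique()
    if len(levels) != 1:
        raise InputError(f"exposure table mixes levels: {sorted(levels)}")
    out = pd.DataFrame({
        "level": exposure_table["level"].to_numpy(),
        "unit_id": exposure_table["unit_id"].to_numpy(),
        "decile_ej": to_deciles(exposure_table["ej_screen"]),
        "decile_density": to_deciles(exposure_table["aadt_density"]),
        "decile_parcel": to_deciles(exposure_table["parcel_proximity"]),
    })
    return out.sort_values("unit_id", ignore_index=True)


def assess_agreement(deciles: pd.DataFrame) -> List[AgreementResult]:
    """Agreement of each candidate measure with the parcel reference.

    One :class:`AgreementResult` per candidate (EJScreen proximity, AADT
    density), computed on the decile table of a single geographic level.
    """
    missing = set(DECILE_COLUMNS) - set(deciles.columns)
    if missing:
        raise InputError(f"decile table missing columns: {sorted(missing)}")
    levels = deciles["level"].unique()
    if len(levels) != 1:
        raise InputError(f"decile table mixes levels: {sorted(levels)}")
    level = str(levels[0])
    ref = deciles["decile_parcel"].to_numpy()
    results = []
    for measure in CANDIDATE_MEASURES:
        cand = deciles[_MEASURE_TO_DECILE[measure]].to_numpy()
        results.append(
            AgreementResult(
                level=level,
                measure=measure,
                good_agreement_fraction=good_agreement(cand, ref),
                kappa=cohens_kappa(cand, ref),
                tau=kendall_tau(cand, ref),
                n_units=len(ref),
            )
        )
    return results
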