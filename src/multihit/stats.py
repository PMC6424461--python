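"""Correlation analyses reported alongside the multi-hit model.

Two uses: (a) per-cancer-type Pearson correlation between somatic
mutation burden and age at diagnosis — weak in tumor cohorts, because
mutation-rate variation between individuals swamps the within-individual
accumulation with age; (b) correlation of the fitted number of hits with
external covariates such as lifetime stem-cell divisions, supplied as a
plain two-column table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import MutationCountCohort

logger = logging.getLogger(__name__)

__all__ = ["CorrelationResult", "pearson_with_p", "fisher_z_interval", "burden_age_correlation"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    ci_low: float
    ci_high: float
    method_notes: str = ""


def pearson_with_p(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value.

    p comes from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom;
    the 95% CI is the Fisher-z interval (NaN bounds when n < 4 or |r| = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for constant input")
    r, p = sps.pearsonr(x, y)
    if n >= 4 and abs(r) < 1.0:
        lo, hi = fisher_z_interval(float(r), n)
    else:
        lo, hi = float("nan"), float("nan")
    return CorrelationResult(
        r=float(r),
        n=int(n),
        p_value=float(p),
        ci_low=lo,
        ci_high=hi,
        method_notes="two-sided t-distribution p-value; Fisher z 95% CI",
    )


def fisher_z_interval(r: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Fisher z confidence interval for a Pearson correlation.

    z = atanh(r) is approximately normal with standard error
    1/sqrt(n-3); the interval is tanh(z -+ z_crit/sqrt(n-3)).
    """
    if n < 4:
        raise ValueError(f"Fisher z interval requires n >= 4, got {n}")
    if not -1.0 < r < 1.0:
        raise ValueError(f"r must lie strictly in (-1, 1), got {r}")
    z = np.arctanh(r)
    z_crit = sps.norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    hw = z_crit / np.sqrt(n - 3)
    return float(np.tanh(z - hw)), float(np.tanh(z + hw))


def burden_age_correlation(
    cohorts: Mapping[str, MutationCountCohort],
    age_column: str = "age_at_diagnosis",
) -> pd.DataFrame:
    """Per-cancer-type correlation of mutation burden with age at diagnosis.

    Samples without an age are dropped (logged); types with fewer than 3
    aged samples, or with constant burden or age, are skipped.  The
    result is sorted by r for plotting.
    """
    rows = []
    for label, cohort in cohorts.items():
        if cohort.metadata is None or age_column not in cohort.metadata.columns:
            logger.warning("cohort %s has no %s metadata; skipped", label, age_column)
            continue
        age = pd.to_numeric(cohort.metadata[age_column], errors="coerce").to_numpy()
        ok = ~np.isnan(age)
        n_drop = int((~ok).sum())
        if n_drop:
            logger.info("cohort %s: dropped %d sample(s) without age", label, n_drop)
        if ok.sum() < 3:
            logger.warning("cohort %s has <3 aged samples; skipped", label)
            continue
        counts = cohort.counts[ok].astype(float)
        if np.ptp(counts) == 0 or np.ptp(age[ok]) == 0:
            logger.warning("cohort %s has constant burden or age; skipped", label)
            continue
        res = pearson_with_p(counts, age[ok])
        rows.append(
            {
                "cancer_type": label,
                "r": res.r,
                "n": res.n,
                "p_value": res.p_value,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    if not rows:
        raise ValueError("no cohort had metadata with enough age values")
    return pd.DataFrame(rows).sort_values("r").reset_index(drop=True)
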