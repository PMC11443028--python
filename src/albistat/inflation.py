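"""Genomic inflation factor from neutral-marker association statistics.

Population stratification inflates case-control test statistics
genome-wide. The median-based inflation factor divides the median of the
per-marker 1-df chi-square statistics by the null chi-square(1) median
(~0.4549); values near 1 indicate limited confounding by ancestry. Each
marker statistic is the penalized likelihood-ratio statistic from a
single-marker Firth model (case/control ~ allele dosage), keeping the
statistic family consistent with the genotype-group analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .firth import FirthOptions, fit_firth, penalized_lrt_pvalue

__all__ = ["CHI2_1_MEDIAN", "MarkerStat", "LambdaResult",
           "marker_chisq", "lambda_median", "marker_panel_lambda"]

CHI2_1_MEDIAN = 0.4549364231  # chi-square(1) median


@dataclass(frozen=True)
class MarkerStat:
    marker_id: str
    chisq: float

    def __post_init__(self) -> None:
        if self.chisq < 0:
            raise ValueError(f"chisq must be non-negative, got {self.chisq}")


@dataclass
class LambdaResult:
    lambda_median: float
    n_markers: int
    per_marker: list[MarkerStat] = field(default_factory=list)


def marker_chisq(
    y: np.ndarray,
    dosage: np.ndarray,
    marker_id: str = "",
    options: FirthOptions | None = None,
    covariates: np.ndarray | None = None,
) -> MarkerStat | None:
    """Penalized LRT statistic for one marker.

    ``y`` is the 0/1 case indicator and ``dosage`` the 0/1/2 allele count.
    Monomorphic markers are excluded (returns None with a warning).
    Covariate columns, if given, enter both the full and restricted fits.
    """
    dosage = np.asarray(dosage, dtype=float)
    if dosage.min() == dosage.max():
        warnings.warn(f"marker {marker_id or '?'} is monomorphic; excluded",
                      RuntimeWarning)
        return None
    cols = [np.ones(len(y)), dosage]
    names = ["intercept", "dosage"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == len(y):
            cov = cov.T
        for k, c in enumerate(cov):
            cols.append(c)
            names.append(f"cov{k}")
    X = np.column_stack(cols)
    fit = fit_firth(X, np.asarray(y, dtype=float), options=options, names=names)
    _, stat, _ = penalized_lrt_pvalue(X, np.asarray(y, dtype=float), fit, 1,
                                      options=options)
    return MarkerStat(marker_id=marker_id, chisq=stat)


def lambda_median(stats: list[MarkerStat]) -> LambdaResult:
    """Median-based genomic inflation factor.

    lambda = median(chisq) / chi2_1 median; the median of an even-length
    list is the midpoint mean. Permutation-invariant and linear in a
    common scaling of the statistics.
    """
    if not stats:
        raise ValueError("need at least one marker statistic")
    med = float(np.median([s.chisq for s in stats]))
    return LambdaResult(lambda_median=med / CHI2_1_MEDIAN,
                        n_markers=len(stats), per_marker=list(stats))


def marker_panel_lambda(
    cohort: pd.DataFrame,
    markers: pd.DataFrame,
    options: FirthOptions | None = None,
) -> LambdaResult:
    """Per-marker Firth tests over a dosage panel, then the inflation factor."""
    y = (cohort["label"] == "case").to_numpy(dtype=float)
    stats = []
    for col in markers.columns:
        st = marker_chisq(y, markers[col].to_numpy(), marker_id=col, options=options)
        if st is not None:
            stats.append(st)
    return lambda_median(stats)
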