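"""Quantitative-trait arm: ophthalmic-comorbidity exclusion, rank-based
group comparisons with Benjamini-Hochberg adjustment, covariate-adjusted
linear trait models, and contingency-table odds ratios.

Visual acuity (LogMAR, higher = worse) and central retinal thickness
(µm, thicker = more foveal underdevelopment) are albinism
endophenotypes; the analysis compares their distributions across the
TYR/OCA2 genotype groups A-D. Because the trait distributions deviate
from normality, the primary comparison is the tie-corrected
Kruskal-Wallis test, with pairwise two-group tests BH-adjusted within a
trait; an ordinary least-squares model with sex and modifier-allele
covariates serves as a parametric companion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "KWResult", "ContingencyTable", "ophthalmic_exclusion", "kruskal_wallis",
    "bh_adjust", "pairwise_group_tests", "linear_trait_model",
    "contingency_or", "box_summary",
]

ALBINISM_ICD10 = "E70.3"
# ICD-10 Chapter VII "Diseases of the eye and adnexa" spans H00-H59
EYE_CHAPTER_PREFIXES = tuple(f"H{d}" for d in range(6))


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a/b = exposed cases/controls, c/d = unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


def ophthalmic_exclusion(
    cohort,
    albinism_code: str = ALBINISM_ICD10,
    eye_prefixes: tuple[str, ...] = EYE_CHAPTER_PREFIXES,
):
    """Drop individuals with eye-chapter ICD codes unless coded for albinism.

    An individual with any ICD-10 code from the eye-and-adnexa chapter
    (default prefixes H0-H5) is removed unless they also carry the
    albinism code E70.3 — so trait differences are not driven by
    unrelated ophthalmic disease. Accepts a list of IndividualRecord or a
    DataFrame with an ``icd_codes`` column of iterables.
    """
    def keep(codes) -> bool:
        codes = set(codes)
        if albinism_code in codes:
            return True
        return not any(c.startswith(eye_prefixes) for c in codes)

    if isinstance(cohort, pd.DataFrame):
        mask = cohort["icd_codes"].map(keep)
        return cohort.loc[mask].reset_index(drop=True)
    return [ind for ind in cohort if keep(ind.icd_codes)]


def kruskal_wallis(values_by_group: dict[str, np.ndarray]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H test across genotype groups."""
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    empty = [g for g, v in values_by_group.items() if len(v) == 0]
    if empty:
        raise ValueError(f"empty groups: {empty}")
    samples = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if all(np.array_equal(s, samples[0]) for s in samples[1:]):
        # identical samples: rank sums are equal by construction
        return KWResult(H=0.0, df=len(samples) - 1, p=1.0)
    H, p = stats.kruskal(*samples)
    return KWResult(H=float(H), df=len(samples) - 1, p=float(p))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1; output order
    matches input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def pairwise_group_tests(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """All unordered two-group comparisons with BH adjustment.

    Each pair is tested with the two-group Kruskal-Wallis statistic
    (equivalent to a Wilcoxon rank-sum without continuity correction);
    raw p-values are BH-adjusted across the pairs of this one trait.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi, gj = groups[i], groups[j]
            res = kruskal_wallis({gi: values_by_group[gi], gj: values_by_group[gj]})
            rows.append({"group_i": gi, "group_j": gj, "p_raw": res.p})
    table = pd.DataFrame(rows)
    table["p_bh"] = bh_adjust(table["p_raw"].to_numpy())
    return table


def linear_trait_model(
    table: pd.DataFrame,
    trait: str,
    include_covariates: bool = True,
) -> pd.DataFrame:
    """OLS of a trait on genotype-group indicators plus covariates.

    Treatment coding with group A as reference; covariates are sex
    (male = 1) and the modifier-allele count. Returns estimates,
    standard errors and t-based p-values per column; rank-deficient
    designs raise an error naming the aliased columns.
    """
    from .firth import build_group_design

    X, names, _ = build_group_design(table, include_covariates=include_covariates)
    y = table[trait].to_numpy(dtype=float)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        aliased = [names[j] for j in sorted(piv[rank:])]
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tval = beta / se
    pval = 2 * stats.t.sf(np.abs(tval), df=n - k)
    return pd.DataFrame({"term": names, "estimate": beta, "se": se,
                         "t": tval, "p": pval})


def contingency_or(table: ContingencyTable) -> dict[str, float]:
    """Raw and Haldane-corrected odds ratios with a Fisher exact p-value.

    or_raw = ad/bc (inf when bc = 0, NaN for 0/0); or_haldane adds 1/2 to
    every cell and coincides with the Firth estimate of the saturated 2x2
    logistic model; the two-sided Fisher p sums hypergeometric tables
    with point probability not exceeding the observed one.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    num, den = a * d, b * c
    if den > 0:
        or_raw = num / den
    elif num > 0:
        or_raw = float("inf")
    else:
        or_raw = float("nan")
    or_haldane = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    _, p_fisher = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {"or_raw": or_raw, "or_haldane": or_haldane,
            "p_fisher": float(p_fisher),
            "raw_defined": den > 0}


def box_summary(values: np.ndarray) -> dict[str, float]:
    """Quartiles, median and Tukey whiskers (most extreme non-outliers)."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {"q1": q1, "median": med, "q3": q3,
            "whisker_lo": float(inside.min()), "whisker_hi": float(inside.max()),
            "n": int(v.size)}
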