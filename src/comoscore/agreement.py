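"""Correlation and concordance between comorbidity indices.

Two statistics per index pair, both computed on the quartile strata (1-4) by
default:

* Spearman's rho — Pearson correlation of mid-ranks (average ranks under
  ties), with a two-sided p from the large-sample t approximation on n-2
  degrees of freedom;
* ICC(A,1) — the intraclass correlation for two fixed raters under the
  absolute-agreement definition (McGraw & Wong two-way model, single
  measurement). Unlike the consistency ICC it penalizes a systematic offset
  between the two instruments. The 95% CI and the p-value against ICC = 0
  use the F-based method.

Each statistic also gets a qualitative label from the conventional verbal
scales (rho: none/poor/fair/moderate/very strong/perfect; ICC, after Fleiss:
poor / fair to good / excellent). The verbal scales leave gaps between named
bands; a value falling in a gap takes the nearer band's label, ties going to
the stronger band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedStatisticError, ValidationError

# (low, high, label) bands of the verbal scales; gap values -> nearest band.
RHO_BANDS = [
    (0.0, 0.0, "none"),
    (0.1, 0.2, "poor"),
    (0.3, 0.5, "fair"),
    (0.6, 0.7, "moderate"),
    (0.8, 0.9, "very strong"),
    (1.0, 1.0, "perfect"),
]
ICC_BANDS = [
    (-np.inf, 0.40, "poor"),
    (0.41, 0.75, "fair to good"),
    (0.75, np.inf, "excellent"),
]


@dataclass(frozen=True)
class AgreementResult:
    pair: tuple[str, str]
    rho: float
    rho_p: float
    icc_a: float
    icc_ci: tuple[float, float]
    icc_p: float
    qualitative_label_rho: str | None = None
    qualitative_label_icc: str | None = None


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks and t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("length mismatch")
    if x.size < 3:
        raise ValidationError("need n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedStatisticError("zero variance in a ranked vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def icc_absolute(x, y, alpha: float = 0.05) -> tuple[float, float, float, float]:
    """ICC(A,1) for two fixed raters, from the two-way ANOVA decomposition.

    Returns ``(icc_a, ci_low, ci_high, p)``. The point estimate is
    (MSR - MSE) / (MSR + MSE + (2/n)(MSC - MSE)) with MSR/MSC/MSE the
    subject, rater and error mean squares; CI by the McGraw & Wong F method,
    p against ICC = 0 from F = MSR/MSE on (n-1, n-1) df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("length mismatch")
    n = x.size
    if n < 5:
        raise ValidationError("need n >= 5")
    k = 2
    data = np.column_stack([x, y])
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    grand = data.mean()
    if np.allclose(row_means, row_means[0]):
        raise UndefinedStatisticError("zero between-subject variance")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    if mse <= 0 and msc <= 0:
        # exact agreement: the interval degenerates to the point estimate
        return float(icc), float(icc), float(icc), 0.0

    # McGraw & Wong (1996) CI for ICC(A,1)
    r = icc
    a = (k * r) / (n * (1.0 - r))
    b = 1.0 + (k * r * (n - 1.0)) / (n * (1.0 - r))
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    if mse <= 0:
        p = 0.0
    else:
        f_stat = msr / mse
        p = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    return float(icc), float(lower), float(upper), p


def _nearest_band(value: float, bands) -> str:
    best_label = None
    best_dist = np.inf
    for lo, hi, label in bands:
        if lo <= value <= hi:
            return label
        d = min(abs(value - lo), abs(value - hi))
        # ties go to the stronger (later) band: <= keeps the last best
        if d <= best_dist:
            best_dist = d
            best_label = label
    return best_label


def label_rho(rho: float) -> str:
    return _nearest_band(min(abs(rho), 1.0), RHO_BANDS)


def label_icc(icc: float) -> str:
    return _nearest_band(icc, ICC_BANDS)


def label_agreement(result: AgreementResult) -> AgreementResult:
    """Attach the verbal-scale labels to a computed result."""
    return replace(
        result,
        qualitative_label_rho=label_rho(result.rho),
        qualitative_label_icc=label_icc(result.icc_a),
    )


def compare_pair(x, y, pair: tuple[str, str]) -> AgreementResult:
    rho, rho_p = spearman_rho(x, y)
    icc, lo, hi, icc_p = icc_absolute(x, y)
    return label_agreement(
        AgreementResult(pair=pair, rho=rho, rho_p=rho_p, icc_a=icc, icc_ci=(lo, hi), icc_p=icc_p)
    )


def agreement_table(strata: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise agreement statistics between the supplied index vectors.

    ``strata`` maps index name -> per-episode stratum (or raw score) vector;
    all vectors must be aligned on the same episodes.
    """
    rows = []
    for a, b in combinations(strata.keys(), 2):
        r = compare_pair(strata[a], strata[b], (a, b))
        rows.append(
            {
                "index_a": a,
                "index_b": b,
                "rho": r.rho,
                "rho_p": r.rho_p,
                "icc_a": r.icc_a,
                "icc_ci_low": r.icc_ci[0],
                "icc_ci_high": r.icc_ci[1],
                "icc_p": r.icc_p,
                "label_rho": r.qualitative_label_rho,
                "label_icc": r.qualitative_label_icc,
            }
        )
    return pd.DataFrame(rows)
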