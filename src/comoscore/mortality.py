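"""Age-adjusted logistic models for in-hospital death, ROC curves, and
DeLong-compared AUCs.

Per comorbidity index the module fits two maximum-likelihood logistic
models, both adjusted for age dichotomized at the cohort median:

* ``ordinal`` — the stratum (1-4) enters as an integer covariate, giving one
  "score (all strata)" odds ratio per unit stratum;
* ``categorical`` — strata 2-4 enter as indicators against stratum 1, giving
  per-stratum odds ratios versus the reference.

Discrimination is summarized by the ROC curve and its AUC (C-statistic),
computed two ways that must agree to machine precision: the trapezoidal
area of the tie-grouped curve and the Mann-Whitney statistic with
half-credit for ties. Paired AUCs are compared with DeLong's nonparametric
method via per-observation placement values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import SeparationError, ValidationError
from .scoring import StrataAssignment

_Z975 = stats.norm.ppf(0.975)


@dataclass
class LogisticFit:
    """A fitted logistic model with its OR table."""

    covariate_spec: str
    covariate_names: list[str]
    coefficients: np.ndarray
    covariance: np.ndarray
    or_table: pd.DataFrame
    log_likelihood: float
    converged: bool
    n_iter: int
    design: np.ndarray = field(repr=False, default=None)


def _check_separation(params: np.ndarray, model, converged: bool) -> None:
    if np.any(np.abs(params) > 15):
        score = model.score(params)
        if np.max(np.abs(score)) > 1e-4 or not converged:
            raise SeparationError(
                "complete or quasi-complete separation (diverging coefficient)"
            )


def _fit_design(X: np.ndarray, y: np.ndarray, names: list[str], spec: str,
                reference_rows: list[tuple[int, str]] | None = None) -> LogisticFit:
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("outcome has a single class")
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=50, tol=1e-10, disp=0)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(str(exc)) from exc
    _check_separation(res.params, model, res.mle_retvals.get("converged", False))
    coefs = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    se = np.sqrt(np.diag(cov))
    rows = []
    for i, name in enumerate(names):
        if name == "intercept":
            continue
        orr = float(np.exp(coefs[i]))
        z = coefs[i] / se[i]
        rows.append(
            {
                "covariate": name,
                "or": orr,
                "ci_low": float(np.exp(coefs[i] - _Z975 * se[i])),
                "ci_high": float(np.exp(coefs[i] + _Z975 * se[i])),
                "p": float(2 * stats.norm.sf(abs(z))),
            }
        )
    table = pd.DataFrame(rows)
    if reference_rows:
        for pos, name in reference_rows:
            ref = pd.DataFrame(
                [{"covariate": name, "or": 1.0, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}]
            )
            table = pd.concat([table.iloc[:pos], ref, table.iloc[pos:]], ignore_index=True)
    return LogisticFit(
        covariate_spec=spec,
        covariate_names=names,
        coefficients=coefs,
        covariance=cov,
        or_table=table,
        log_likelihood=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iter=int(res.mle_retvals.get("iterations", 0)),
        design=np.asarray(X, dtype=float),
    )


def build_design(
    strata: np.ndarray, age: np.ndarray, age_cut: float, strata_coding: str, index_name: str
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the age-adjusted model (intercept first)."""
    strata = np.asarray(strata)
    age_gt = (np.asarray(age) > age_cut).astype(float)
    if strata_coding == "ordinal":
        X = np.column_stack([np.ones(strata.size), strata.astype(float), age_gt])
        names = ["intercept", f"{index_name} score (all strata)", f"age > {age_cut:g}"]
    elif strata_coding == "categorical":
        cols = [np.ones(strata.size)]
        names = ["intercept"]
        for k in (2, 3, 4):
            cols.append((strata == k).astype(float))
            names.append(f"{index_name} strata {k}")
        cols.append(age_gt)
        names.append(f"age > {age_cut:g}")
        X = np.column_stack(cols)
    else:
        raise ValidationError(f"unknown strata coding {strata_coding!r}")
    return X, names


def fit_logistic(
    cohort,
    strata: StrataAssignment,
    strata_coding: str = "ordinal",
    age_cut: float | None = None,
) -> LogisticFit:
    """Fit the age-adjusted in-hospital-death model for one index's strata."""
    y = np.array([e.death for e in cohort.episodes], dtype=float)
    age = np.array([e.age for e in cohort.episodes], dtype=float)
    if len(y) != strata.strata.size:
        raise ValidationError("strata not aligned with cohort")
    if age_cut is None:
        age_cut = cohort.median_age
    X, names = build_design(strata.strata, age, age_cut, strata_coding, strata.index_name)
    ref = None
    if strata_coding == "categorical":
        ref = [(0, f"{strata.index_name} strata 1 (reference)")]
    return _fit_design(X, y, names, strata_coding, reference_rows=ref)


def predict_probability(fit: LogisticFit, X: np.ndarray) -> np.ndarray:
    """Fitted death probabilities logistic(X @ beta)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != fit.coefficients.size:
        raise ValidationError(
            f"design has {X.shape[1]} columns, model has {fit.coefficients.size}"
        )
    eta = X @ fit.coefficients
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class RocResult:
    index_name: str
    predictor_mode: str
    points: np.ndarray  # (fpr, tpr) rows, from (0,0) to (1,1)
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    scores: np.ndarray = field(repr=False, default=None)
    outcome: np.ndarray = field(repr=False, default=None)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _auc_mann_whitney(scores: np.ndarray, outcome: np.ndarray) -> float:
    pos = scores[outcome]
    m, n = pos.size, scores.size - pos.size
    ranks = _midranks(scores)
    return float((ranks[outcome].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_components(scores: np.ndarray, outcome: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive) and V01 (per negative), plus AUC."""
    pos = scores[outcome]
    neg = scores[~outcome]
    m, n = pos.size, neg.size
    tz = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_variance(scores: np.ndarray, outcome: np.ndarray) -> float:
    """DeLong variance of a single AUC."""
    v10, v01, _ = _delong_components(scores, outcome)
    m, n = v10.size, v01.size
    if m < 2 or n < 2:
        return float("nan")
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def roc_curve(scores, outcome, index_name: str = "score",
              predictor_mode: str = "raw_score") -> RocResult:
    """Tie-grouped ROC curve with dual AUC computation.

    Thresholds sweep the distinct score values in descending order; tied
    scores produce diagonal segments. The trapezoidal area and the
    Mann-Whitney AUC (half credit for ties) are both computed and must agree
    to 1e-12; DeLong SE and a Wald 95% CI on the AUC scale are attached.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if scores.shape != outcome.shape:
        raise ValidationError("scores and outcome length mismatch")
    m = int(outcome.sum())
    n = outcome.size - m
    if m == 0 or n == 0:
        raise ValidationError("outcome has a single class")
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = outcome[order]
    # group tied thresholds
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cuts = np.concatenate([distinct, [s_sorted.size - 1]])
    tp = np.cumsum(y_sorted)[cuts]
    fp = (cuts + 1) - tp
    tpr = np.concatenate([[0.0], tp / m, [1.0]])
    fpr = np.concatenate([[0.0], fp / n, [1.0]])
    points = np.column_stack([fpr, tpr])
    auc_trap = float(np.trapezoid(tpr, fpr))
    auc_mw = _auc_mann_whitney(scores, outcome)
    if abs(auc_trap - auc_mw) > 1e-12:
        raise AssertionError(
            f"trapezoid AUC {auc_trap!r} != Mann-Whitney AUC {auc_mw!r}"
        )
    se = float(np.sqrt(delong_variance(scores, outcome)))
    ci = (max(0.0, auc_mw - _Z975 * se), min(1.0, auc_mw + _Z975 * se))
    return RocResult(
        index_name=index_name,
        predictor_mode=predictor_mode,
        points=points,
        auc=auc_mw,
        auc_se=se,
        auc_ci=ci,
        scores=scores,
        outcome=outcome,
    )


@dataclass(frozen=True)
class AucComparison:
    pair: tuple[str, str]
    auc_a: float
    auc_b: float
    auc_diff: float
    variance_of_diff: float
    z: float
    p: float


def delong_auc_test(scores_a, scores_b, outcome, pair: tuple[str, str] = ("a", "b")) -> AucComparison:
    """DeLong's paired test of AUC(a) = AUC(b) on the same episodes."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if not (scores_a.shape == scores_b.shape == outcome.shape):
        raise ValidationError("unpaired inputs (length mismatch)")
    if outcome.all() or not outcome.any():
        raise ValidationError("outcome has a single class")
    v10a, v01a, auc_a = _delong_components(scores_a, outcome)
    v10b, v01b, auc_b = _delong_components(scores_b, outcome)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    S = s10 / m + s01 / n
    var_diff = float(S[0, 0] + S[1, 1] - 2 * S[0, 1])
    diff = auc_a - auc_b
    if var_diff <= 0:
        # degenerate: identical predictors give exactly zero variance
        z = 0.0 if np.isclose(diff, 0.0) else np.inf * np.sign(diff)
        p = 1.0 if np.isclose(diff, 0.0) else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return AucComparison(
        pair=pair, auc_a=auc_a, auc_b=auc_b, auc_diff=diff,
        variance_of_diff=max(var_diff, 0.0), z=float(z), p=p,
    )


@dataclass
class IndexComparison:
    """Full per-index model/ROC outputs plus the pairwise DeLong tests."""

    fits_ordinal: dict[str, LogisticFit]
    fits_categorical: dict[str, LogisticFit]
    rocs: dict[str, RocResult]
    delong: list[AucComparison]
    ranking: list[str]  # index names by descending AUC


def compare_indices(
    cohort,
    strata: dict[str, StrataAssignment],
    predictor_mode: str = "model_probability",
    age_cut: float | None = None,
    scores: pd.DataFrame | None = None,
) -> IndexComparison:
    """Run the full comparison: per-index logistic fits, ROC, DeLong tests.

    ``predictor_mode="model_probability"`` scores each episode with the
    fitted probability of the ordinal model (stratum + age), which is
    monotone in the stratum; ``"raw_score"`` uses the raw index score when
    ``scores`` is supplied, else the stratum itself.
    """
    y = np.array([e.death for e in cohort.episodes], dtype=bool)
    age = np.array([e.age for e in cohort.episodes], dtype=float)
    if age_cut is None:
        age_cut = cohort.median_age
    fits_o: dict[str, LogisticFit] = {}
    fits_c: dict[str, LogisticFit] = {}
    rocs: dict[str, RocResult] = {}
    for name, sa in strata.items():
        fits_o[name] = fit_logistic(cohort, sa, "ordinal", age_cut)
        fits_c[name] = fit_logistic(cohort, sa, "categorical", age_cut)
        if predictor_mode == "model_probability":
            X, _ = build_design(sa.strata, age, age_cut, "ordinal", name)
            pred = predict_probability(fits_o[name], X)
        elif predictor_mode == "raw_score":
            if scores is not None and name in scores.columns:
                pred = scores[name].to_numpy(dtype=float)
            else:
                pred = sa.strata.astype(float)
        else:
            raise ValidationError(f"unknown predictor mode {predictor_mode!r}")
        rocs[name] = roc_curve(pred, y, index_name=name, predictor_mode=predictor_mode)
    names = list(strata.keys())
    delong = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            delong.append(
                delong_auc_test(rocs[a].scores, rocs[b].scores, y, pair=(a, b))
            )
    ranking = sorted(names, key=lambda nm: -rocs[nm].auc)
    return IndexComparison(
        fits_ordinal=fits_o, fits_categorical=fits_c, rocs=rocs,
        delong=delong, ranking=ranking,
    )


def auc_table(rocs: dict[str, RocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "index": name,
                "auc": r.auc,
                "se": r.auc_se,
                "ci_low": r.auc_ci[0],
                "ci_high": r.auc_ci[1],
            }
            for name, r in rocs.items()
        ]
    )


def delong_table(comparisons: list[AucComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "index_a": c.pair[0],
                "index_b": c.pair[1],
                "auc_a": c.auc_a,
                "auc_b": c.auc_b,
                "auc_diff": c.auc_diff,
                "z": c.z,
                "p": c.p,
            }
            for c in comparisons
        ]
    )
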