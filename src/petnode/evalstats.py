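"""Confusion metrics, exact tests, AUC comparison, and log-SUV models.

Confusion cells are real-valued so that expected (fractional) counts from
the combined-test arithmetic flow through the same metric code as integer
tallies.  The weighted exact McNemar test accumulates a configurable
weight on discordant pairs at EBUS-positive nodes, normalises the weights
to sum to the sample size, rounds the discordant totals to integers, and
applies the two-sided exact binomial test (double the smaller tail,
capped at 1).  AUCs and their comparison use the DeLong structural-
components estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .core import Cohort

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "confusion",
    "metrics",
    "reconstruct_confusion",
    "McNemarResult",
    "mcnemar_exact_weighted",
    "fisher_exact_2x2",
    "kruskal_wallis",
    "auc_with_ci",
    "compare_auc_paired",
    "LinearModelFit",
    "fit_log_suv_model",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally; cells may be fractional (expected counts)."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")
        if self.n <= 0:
            raise ValueError("empty confusion table")

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> float:
        return self.tp + self.fn

    @property
    def n_called_positive(self) -> float:
        return self.tp + self.fp


class Metrics(NamedTuple):
    sensitivity: float
    specificity: float
    mcr: float
    fdr: float


def confusion(labels: Sequence[int], calls: Sequence[int]) -> ConfusionCounts:
    labels = np.asarray(labels, int)
    calls = np.asarray(calls, int)
    if labels.shape != calls.shape:
        raise ValueError("labels and calls must have equal length")
    if labels.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum((labels == 1) & (calls == 1)))
    fn = int(np.sum((labels == 1) & (calls == 0)))
    fp = int(np.sum((labels == 0) & (calls == 1)))
    tn = int(np.sum((labels == 0) & (calls == 0)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, misclassification rate, FDR.

    FDR is fp / (fp + tp): false positives over all classifier-positive
    nodes.  A zero denominator yields NaN (undefined marker), never an
    exception.
    """
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return Metrics(
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        mcr=ratio(c.fp + c.fn, c.n),
        fdr=ratio(c.fp, c.fp + c.tp),
    )


def reconstruct_confusion(mcr: float, fn: float, n: float,
                          n_positive: float) -> ConfusionCounts:
    """Rebuild a 2x2 table from a printed (MCR, FN) pair.

    misclassified = round(mcr * n); fp = misclassified - fn;
    tp = n_positive - fn; tn fills the remainder.  Raises on any negative
    derived cell (inconsistent inputs).
    """
    misclassified = round(mcr * n)
    fp = misclassified - fn
    tp = n_positive - fn
    tn = n - n_positive - fp
    if min(fp, tp, tn) < 0:
        raise ValueError("inconsistent (mcr, fn, n, n_positive) combination")
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class McNemarResult:
    discordant_a_only: float
    discordant_b_only: float
    b_star: int
    c_star: int
    weight_mcn: float
    p_value: float
    zero_discordance: bool = False


def mcnemar_exact_weighted(
    calls_a: Sequence[int],
    calls_b: Sequence[int],
    labels: Sequence[int],
    weight_mcn: float = 1.0,
) -> McNemarResult:
    """Weighted exact McNemar test of two classifiers against one label.

    Discordant pairs (exactly one classifier correct) accumulate
    ``weight_mcn`` at label-1 records and 1 at label-0 records; weights
    are normalised to sum to n over all records, the two discordant
    totals are rounded to the nearest integers b*, c*, and the two-sided
    exact binomial p-value is 2 * P(Bin(b*+c*, 1/2) <= min(b*, c*)),
    capped at 1.  With weight 1 this is the classical exact McNemar test.
    """
    a = np.asarray(calls_a, int)
    b = np.asarray(calls_b, int)
    y = np.asarray(labels, int)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("calls and labels must have equal length")
    if weight_mcn <= 0:
        raise ValueError("weight_mcn must be > 0")
    w = np.where(y == 1, weight_mcn, 1.0)
    w = w * (y.size / w.sum())
    correct_a = a == y
    correct_b = b == y
    a_only = float(np.sum(w[correct_a & ~correct_b]))
    b_only = float(np.sum(w[~correct_a & correct_b]))
    b_star = int(round(a_only))
    c_star = int(round(b_only))
    total = b_star + c_star
    if total == 0:
        return McNemarResult(a_only, b_only, b_star, c_star, weight_mcn,
                             p_value=1.0, zero_discordance=True)
    p = min(1.0, 2.0 * float(stats.binom.cdf(min(b_star, c_star), total, 0.5)))
    return McNemarResult(a_only, b_only, b_star, c_star, weight_mcn, p_value=p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities of
    tables, fixed margins, with probability <= observed)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square tail p."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("each group must be nonempty")
    df = uniq.size - 1
    if np.all(values == values[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), df, float(p)


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (V10 per positive, V01 per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # pairwise heaviside with half credit for ties
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return auc, v10, v01


def auc_with_ci(scores: Sequence[float], labels: Sequence[int],
                level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC with a Wald CI from the DeLong variance.

    Returns (nan, (nan, nan)) when one class is absent.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        nan = float("nan")
        return nan, (nan, nan)
    auc, v10, v01 = _delong_components(scores, labels)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(max(var, 0.0))
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, (lo, hi)


def compare_auc_paired(scores_a: Sequence[float], scores_b: Sequence[float],
                       labels: Sequence[int]) -> tuple[float, float]:
    """DeLong paired AUC contrast: chi2 on 1 df for auc_a - auc_b.

    Returns (nan, nan) when the variance of the difference is zero.
    """
    sa = np.asarray(scores_a, float)
    sb = np.asarray(scores_b, float)
    y = np.asarray(labels, int)
    auc_a, va10, va01 = _delong_components(sa, y)
    auc_b, vb10, vb01 = _delong_components(sb, y)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    var_diff = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var_diff <= 0:
        if auc_a == auc_b:  # identical score vectors: no difference to test
            return 0.0, 1.0
        nan = float("nan")
        return nan, nan
    chi2 = (auc_a - auc_b) ** 2 / var_diff
    return float(chi2), float(stats.chi2.sf(chi2, 1))


@dataclass
class LinearModelFit:
    """OLS fit on log SUVmax with drop-term (Type III) F tests."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    f_tests: dict[str, tuple[float, int, int, float]]  # F, df_num, df_den, p
    residual_variance: float
    r_fit: float


def _drop_term_f(y, X_full, term_cols):
    """F test comparing the full model to the model without a term."""
    n, p = X_full.shape
    beta_full, rss_full = _ols(y, X_full)
    keep = [j for j in range(p) if j not in term_cols]
    _, rss_red = _ols(y, X_full[:, keep])
    df_num = len(term_cols)
    df_den = n - p
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    return max(float(f), 0.0), df_num, df_den, float(stats.f.sf(max(f, 0.0), df_num, df_den))


def _ols(y, X):
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_log_suv_model(
    cohort: Cohort,
    form: Literal["intra_patient", "primary_covariance"] = "primary_covariance",
    use_truth: bool | None = None,
) -> LinearModelFit:
    """Linear models for the log SUVmax of involved nodes.

    ``primary_covariance``: log(suv) ~ log(primary suv) + echelon dummies;
    recovers the log-log slope and the echelon offsets.  ``intra_patient``:
    log(suv) ~ patient + echelon factors, isolating the within-patient
    echelon effect.  Models are fit on truth-positive nodes when the
    cohort carries truth (overridable), else on EBUS-positive nodes.
    F tests are drop-term: the full model against the model with the
    term's columns removed.
    """
    if use_truth is None:
        use_truth = cohort.has_truth
    recs = [
        r for r in cohort
        if (r.truth_positive if use_truth else r.ebus_positive)
    ]
    echelons = sorted({r.echelon for r in recs})
    if len(echelons) < 2:
        raise ValueError("need involved nodes on at least two echelons")
    y = np.log([r.suv_max for r in recs])
    # echelon dummies with the lowest present echelon as reference
    ech_cols = []
    ech_names = []
    for e in echelons[1:]:
        ech_cols.append(np.array([1.0 if r.echelon == e else 0.0 for r in recs]))
        ech_names.append(f"ech{e}")

    if form == "primary_covariance":
        logp = np.log([r.suv_max_primary for r in recs])
        X = np.column_stack([np.ones(len(recs)), logp, *ech_cols])
        names = ["intercept", "log_suv_primary", *ech_names]
        terms = {"log_suv_primary": [1],
                 "echelon": list(range(2, 2 + len(ech_cols)))}
    elif form == "intra_patient":
        pids = sorted({r.patient_id for r in recs})
        if len(pids) < 2:
            raise ValueError("intra-patient form needs >= 2 patients")
        pat_cols = []
        pat_names = []
        for pid in pids[1:]:  # first patient is reference
            pat_cols.append(np.array([1.0 if r.patient_id == pid else 0.0 for r in recs]))
            pat_names.append(f"patient[{pid}]")
        X = np.column_stack([np.ones(len(recs)), *pat_cols, *ech_cols])
        names = ["intercept", *pat_names, *ech_names]
        terms = {
            "patient": list(range(1, 1 + len(pat_cols))),
            "echelon": list(range(1 + len(pat_cols), 1 + len(pat_cols) + len(ech_cols))),
        }
    else:
        raise ValueError(f"unknown form {form!r}")

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("model is not identifiable (rank-deficient design)")

    beta, rss = _ols(y, X)
    df_den = len(recs) - X.shape[1]
    if df_den <= 0:
        raise ValueError("not enough residual degrees of freedom")
    sigma2 = rss / df_den
    cov = sigma2 * np.linalg.inv(X.T @ X)
    ses = np.sqrt(np.diag(cov))
    fitted = X @ beta
    r_fit = float(np.corrcoef(fitted, y)[0, 1]) if np.std(fitted) > 0 else 0.0
    f_tests = {name: _drop_term_f(y, X, cols) for name, cols in terms.items()}
    return LinearModelFit(
        coefficients=dict(zip(names, beta)),
        standard_errors=dict(zip(names, ses)),
        f_tests=f_tests,
        residual_variance=float(sigma2),
        r_fit=r_fit,
    )
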