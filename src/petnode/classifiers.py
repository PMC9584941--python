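"""Classifiers scoring the probability of EBUS-positivity of a node.

The weighted logistic model is the reference method and is fit from first
principles by iteratively reweighted least squares (IRLS) with
step-halving, because the case-weighting scheme (raw weight ``w`` on
EBUS-positive nodes, 1 on negatives, normalised so weights sum to the
sample size) is the lever through which classifier sensitivity is
calibrated.  Tree-ensemble and feed-forward backends come from
scikit-learn behind a shared probabilistic-scorer contract.

Design encoding: echelon enters with reference (dummy) coding, echelon-1
as baseline, plus SUVmax x echelon interaction products; covariates enter
untransformed (raw SUV units and cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit
from scipy.linalg import qr as scipy_qr
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier

from .core import Cohort, LymphNodeRecord

__all__ = [
    "DESIGN_COLUMNS",
    "build_design",
    "design_matrix",
    "CaseWeights",
    "make_weights",
    "LogisticModel",
    "SeparationError",
    "SingularityError",
    "fit_weighted_logistic",
    "logistic_trainer",
    "predict_prob",
    "wald_tests",
    "fit_probabilistic_backend",
    "ImportanceReport",
    "variable_importance",
]

DESIGN_COLUMNS = [
    "intercept",
    "suv_max",
    "ct_sd",
    "suv_max_primary",
    "ech2",
    "ech3",
    "suv_x_ech2",
    "suv_x_ech3",
    "station4R_left",
    "largest_suv_e2",
    "conglomerate",
    "histology_adeno",
    "primary_right",
]

#: Multi-column terms tested jointly in Wald tests (echelon contrasts and
#: the SUVmax x echelon interaction pair); all other columns are 1-df.
JOINT_TERMS = {
    "echelon": ("ech2", "ech3"),
    "suv_x_echelon": ("suv_x_ech2", "suv_x_ech3"),
}


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: coefficients diverge."""


class SingularityError(np.linalg.LinAlgError):
    """Design matrix is rank deficient on the weighted support."""


def build_design(record: LymphNodeRecord) -> np.ndarray:
    """Encode one node as a design row aligned to :data:`DESIGN_COLUMNS`."""
    ech2 = 1.0 if record.echelon == 2 else 0.0
    ech3 = 1.0 if record.echelon == 3 else 0.0
    return np.array(
        [
            1.0,
            record.suv_max,
            record.short_diameter_cm,
            record.suv_max_primary,
            ech2,
            ech3,
            record.suv_max * ech2,
            record.suv_max * ech3,
            float(record.station4R_left_primary),
            record.largest_suv_echelon2,
            float(record.conglomerate),
            float(record.histology_adeno),
            float(record.primary_right_sided),
        ]
    )


def design_matrix(cohort: Cohort) -> np.ndarray:
    return np.vstack([build_design(r) for r in cohort])


@dataclass(frozen=True)
class CaseWeights:
    """Per-record raw and normalised case weights."""

    raw: np.ndarray
    normalised: np.ndarray


def make_weights(labels: Sequence[int], positive_weight: float) -> CaseWeights:
    """Weight ``positive_weight`` on label 1, 1 on label 0, then normalise
    so the weights sum to the sample size."""
    if positive_weight <= 0:
        raise ValueError("positive_weight must be > 0")
    y = np.asarray(labels, dtype=float)
    if y.size == 0:
        raise ValueError("labels must be nonempty")
    raw = np.where(y == 1, positive_weight, 1.0)
    normalised = raw * (y.size / raw.sum())
    return CaseWeights(raw=raw, normalised=normalised)


@dataclass
class LogisticModel:
    """Weighted-logistic fit: coefficients, convergence state, covariance."""

    coefficients: np.ndarray
    converged: bool
    iterations: int
    covariance: np.ndarray
    column_names: tuple[str, ...] = tuple(DESIGN_COLUMNS)


def _weighted_loglik(beta, X, y, w):
    eta = X @ beta
    # log(1+exp) computed stably
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_weighted_logistic(
    X: np.ndarray,
    y: Sequence[int],
    weights: CaseWeights | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 100.0,
) -> LogisticModel:
    """Maximise the weighted Bernoulli log-likelihood by IRLS.

    Convergence when the largest coefficient change falls below ``tol``;
    step-halving protects against likelihood decrease.  Separation is
    detected when any coefficient exceeds ``separation_bound`` on
    internally standardised inputs.  The covariance is the inverse of the
    weighted Fisher information at the optimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights.normalised, float)
    n, p = X.shape
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    if np.linalg.matrix_rank(X * np.sqrt(w)[:, None]) < p:
        raise SingularityError("design is rank deficient on the weighted support")

    beta = np.zeros(p)
    ll = _weighted_loglik(beta, X, y, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        wv = w * mu * (1.0 - mu)
        info = X.T @ (X * wv[:, None])
        grad = X.T @ (w * (y - mu))
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            # fitted probabilities at 0/1 can make the information singular
            # even for a full-rank design; fall back to a least-squares step
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving on likelihood decrease
        alpha = 1.0
        for _ in range(30):
            candidate = beta + alpha * step
            ll_new = _weighted_loglik(candidate, X, y, w)
            if ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        delta = alpha * step
        beta = beta + delta
        ll_prev, ll = ll, _weighted_loglik(beta, X, y, w)
        if np.max(np.abs(beta * scale)) > separation_bound:
            raise SeparationError(
                "coefficients diverging: complete or quasi-complete separation"
            )
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
        # a flat likelihood with still-moving coefficients signals a
        # quasi-separated direction (a rare flag perfectly predictive in
        # sample); the fit is converged in every direction that matters
        if abs(ll - ll_prev) < 1e-12 * (abs(ll) + 1.0) and it > 1:
            converged = True
            break

    mu = expit(X @ beta)
    info = X.T @ (X * (w * mu * (1.0 - mu))[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return LogisticModel(coefficients=beta, converged=converged,
                         iterations=it, covariance=cov)


def predict_prob(model: LogisticModel, design) -> np.ndarray | float:
    """Inverse-logit of the linear predictor; scalar for one row."""
    design = np.asarray(design, dtype=float)
    eta = design @ model.coefficients
    p = expit(eta)
    return float(p) if np.ndim(p) == 0 else p


def wald_tests(model: LogisticModel) -> dict[str, tuple[float, int, float]]:
    """Per-term Wald chi-square tests: (chi2, df, p) per term.

    Single-df terms use (beta/se)^2; the echelon contrasts and the
    SUVmax x echelon interaction pair are tested jointly with 2 df.
    """
    cols = list(model.column_names)
    cov = model.covariance
    if not np.all(np.isfinite(cov)):
        raise SingularityError("covariance is not finite")
    out: dict[str, tuple[float, int, float]] = {}
    grouped = {c for cs in JOINT_TERMS.values() for c in cs}
    for name, members in JOINT_TERMS.items():
        idx = [cols.index(c) for c in members]
        b = model.coefficients[idx]
        sub = cov[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(sub, b))
        df = len(idx)
        out[name] = (chi2, df, float(stats.chi2.sf(chi2, df)))
    for j, name in enumerate(cols):
        if name in grouped:
            continue
        se = math.sqrt(cov[j, j])
        chi2 = (model.coefficients[j] / se) ** 2 if se > 0 else 0.0
        out[name] = (float(chi2), 1, float(stats.chi2.sf(chi2, 1)))
    return out


def logistic_trainer(positive_weight: float = 1.0, tol: float = 1e-8,
                     max_iter: int = 100):
    """Trainer closure for cross-validation pipelines.

    Small training subsets can leave a rare binary column constant (no
    conglomerate node in the subset, say); the trainer keeps a maximal
    linearly independent column set (pivoted QR) and fits the weighted
    logistic model on it, so every fold trains on an identifiable design.
    """

    def train(X, y):
        X = np.asarray(X, dtype=float)
        _, r, piv = scipy_qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        cut = diag[0] * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int(np.sum(diag > max(cut, 1e-10 * diag[0]))) if diag.size else 0
        keep = np.sort(piv[:rank])
        cw = make_weights(y, positive_weight)
        try:
            model = fit_weighted_logistic(X[:, keep], y, cw, tol=tol,
                                          max_iter=max_iter)
        except SeparationError:
            # a fold with, say, no positive echelon-3 node quasi-separates;
            # run the monotone IRLS to its iteration cap instead — the
            # saturated probabilities are exactly what scoring needs
            model = fit_weighted_logistic(X[:, keep], y, cw, tol=tol,
                                          max_iter=max_iter,
                                          separation_bound=float("inf"))

        def scorer(Xt):
            Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
            eta = Xt[:, keep] @ model.coefficients
            return expit(eta)

        scorer.model = model
        scorer.columns = keep
        return scorer

    return train


class _ConstantScorer:
    def __init__(self, value: float):
        self.value = float(value)

    def __call__(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.full(X.shape[0], self.value)


class _SklearnScorer:
    """Probability scorer wrapping a fitted scikit-learn estimator."""

    def __init__(self, estimator):
        self.estimator = estimator
        self._pos_col = int(np.where(estimator.classes_ == 1)[0][0])

    def __call__(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.estimator.predict_proba(X)[:, self._pos_col]


def fit_probabilistic_backend(
    kind: str,
    X: np.ndarray,
    y: Sequence[int],
    weights: CaseWeights | None = None,
    hyperparams: dict | None = None,
    seed: int = 0,
):
    """Fit a tree-ensemble or feed-forward scorer.

    Defaults: 200 trees for the ensemble; four hidden layers of 8 units
    for the feed-forward network.  The feed-forward backend realises case
    weights by integer row replication (raw weights rounded), since its
    optimiser takes no per-sample weights; the tree ensemble accepts them
    natively.  The returned scorer maps a design matrix to probabilities
    in [0, 1] and is deterministic under the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    hp = dict(hyperparams or {})
    if kind not in ("tree_ensemble", "feedforward"):
        raise ValueError(f"unknown backend kind {kind!r}")
    if len(np.unique(y)) < 2:
        return _ConstantScorer(float(y[0]) if y.size else 0.0)
    if kind == "tree_ensemble":
        est = RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 200),
            random_state=seed,
            **hp,
        )
        sample_weight = None if weights is None else weights.normalised
        est.fit(X, y, sample_weight=sample_weight)
        return _SklearnScorer(est)
    if kind == "feedforward":
        est = MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (8, 8, 8, 8)),
            max_iter=hp.pop("max_iter", 500),
            random_state=seed,
            **hp,
        )
        if weights is not None:
            reps = np.maximum(np.rint(weights.raw).astype(int), 1)
            X = np.repeat(X, reps, axis=0)
            y = np.repeat(y, reps)
        est.fit(X, y)
        return _SklearnScorer(est)
    raise ValueError(f"unknown backend kind {kind!r}")


@dataclass
class ImportanceReport:
    """Variable importance: structural split counts plus held-out loss
    reduction (log-loss increase under permutation; may be negative)."""

    variables: tuple[str, ...]
    split_counts: np.ndarray
    loss_reduction: np.ndarray
    method: str = "permutation"

    def as_rows(self) -> list[tuple[str, int, float]]:
        order = np.argsort(-self.loss_reduction)
        return [
            (self.variables[i], int(self.split_counts[i]), float(self.loss_reduction[i]))
            for i in order
        ]


def _log_loss(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def variable_importance(
    scorer,
    X: np.ndarray,
    y: Sequence[int],
    feature_names: Sequence[str] | None = None,
    n_repeats: int = 5,
    seed: int = 0,
) -> ImportanceReport:
    """Split counts from the ensemble structure and permutation loss
    reduction on the supplied (held-out) data.

    For a backend without introspectable tree structure the split counts
    are zero and the report is flagged ``permutation-only``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{j}" for j in range(X.shape[1])
    )
    split_counts = np.zeros(X.shape[1], dtype=int)
    method = "permutation-only"
    est = getattr(scorer, "estimator", None)
    if est is not None and hasattr(est, "estimators_"):
        for tree in est.estimators_:
            feats = tree.tree_.feature
            used = feats[feats >= 0]
            np.add.at(split_counts, used, 1)
        method = "splits+permutation"
    rng = np.random.default_rng(seed)
    base = _log_loss(y, scorer(X))
    reduction = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        losses = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            losses.append(_log_loss(y, scorer(Xp)))
        reduction[j] = float(np.mean(losses) - base)
    return ImportanceReport(
        variables=names, split_counts=split_counts,
        loss_reduction=reduction, method=method,
    )
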