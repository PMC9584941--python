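"""Synthetic node-level cohorts for stage-III NSCLC staging experiments.

The generator emulates the statistical structure of a 180-patient cohort
with ~675 EBUS-sampled lymph nodes spread over three drainage echelons
(expected counts 169/297/209), involvement prevalences 86%/42%/9.6%, and
log-normal SUVmax and short-axis diameter distributions matched to the
published per-echelon/per-status quantiles.  The SUVmax of an involved
node depends on the primary tumour's SUVmax on the log scale (slope 0.55)
with additive echelon offsets (-0.328 for echelon-2, -0.422 for
echelon-3 relative to echelon-1).  A latent-truth layer is observed
through EBUS-TBNA with configurable sensitivity and perfect specificity.

Distribution family
-------------------
Every positive continuous quantity is log-normal, consistent with the
observation that the log SUVmax of involved nodes is approximately
normal.  Parameters are pinned from published quantiles: the median fixes
``mu = ln(median)`` and one symmetric quantile pair fixes
``sigma = (ln q_high - ln q_low) / (z(p_high) - z(p_low))``.

Randomness
----------
A single root seed is split into one child stream per patient
(``numpy.random.SeedSequence.spawn``); within a patient, draws follow a
documented order (primary SUV, laterality, histology, node counts, then
nodes echelon-ascending), so that adding downstream features never
perturbs earlier draws.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import stats

from .core import Cohort, LymphNodeRecord, CONGLOMERATE_MIN_DIAMETER_CM

__all__ = [
    "QuantileSpec",
    "CohortConfig",
    "lognormal_from_quantiles",
    "calibrate_positive_intercept",
    "generate_cohort",
]

#: EBUS only samples nodes with short-axis diameter of 5 mm or more.
MIN_NODE_DIAMETER_CM = 0.5


@dataclass(frozen=True)
class QuantileSpec:
    """A median plus one symmetric quantile pair of a positive quantity."""

    median: float
    q_low: float
    q_high: float
    p_low: float = 0.25
    p_high: float = 0.75

    def __post_init__(self):
        if not (0 < self.p_low < self.p_high < 1):
            raise ValueError("require 0 < p_low < p_high < 1")
        if not (self.q_low <= self.median <= self.q_high):
            raise ValueError("require q_low <= median <= q_high")
        if self.median <= 0 or self.q_low <= 0:
            raise ValueError("quantiles must be positive")


def lognormal_from_quantiles(spec: QuantileSpec) -> tuple[float, float]:
    """Fit (mu, sigma) of a log-normal from a median and a quantile pair.

    The median pins ``mu = ln(median)`` exactly; the spread of the quantile
    pair pins ``sigma``.  Degenerate spread (q_low == q_high == median)
    yields sigma = 0.
    """
    if spec.q_low == spec.q_high:
        if spec.q_low != spec.median:
            raise ValueError("q_low == q_high != median is infeasible")
        return math.log(spec.median), 0.0
    z_span = stats.norm.ppf(spec.p_high) - stats.norm.ppf(spec.p_low)
    sigma = (math.log(spec.q_high) - math.log(spec.q_low)) / z_span
    return math.log(spec.median), sigma


def calibrate_positive_intercept(
    slope: float, mu_primary: float, target_median_e1: float
) -> float:
    """Intercept making the median echelon-1 positive SUVmax hit a target.

    With log suv = b0 + slope * log(primary) + noise and the primary at its
    median, b0 = ln(target) - slope * mu_primary.
    """
    if target_median_e1 <= 0:
        raise ValueError("target median must be positive")
    return math.log(target_median_e1) - slope * mu_primary


# --- published marginal quantiles used for the defaults -------------------

PRIMARY_SUV_SPEC = QuantileSpec(14.65, 4.85, 30.35, 0.05, 0.95)
NEGATIVE_SUV_SPEC = QuantileSpec(2.43, 0.90, 5.30, 0.05, 0.95)
# echelon-1 positive SUVmax quartiles; pins the marginal spread used in the
# residual-variance decomposition below
E1_POSITIVE_SUV_SPEC = QuantileSpec(10.6, 6.5, 16.0)

DIAMETER_SPECS: dict[tuple[int, int], QuantileSpec] = {
    (1, 1): QuantileSpec(2.04, 1.29, 6.00),
    (1, 0): QuantileSpec(0.92, 0.62, 1.24),
    (2, 1): QuantileSpec(1.63, 1.29, 2.15),
    (2, 0): QuantileSpec(1.02, 0.78, 1.34),
    (3, 1): QuantileSpec(1.66, 1.28, 1.90),
    (3, 0): QuantileSpec(0.79, 0.60, 1.06),
}


def _default_sigma_res(slope: float) -> float:
    """Residual log-SUV sd by variance decomposition.

    The marginal sd of log SUVmax of echelon-1 positives (from the quartile
    ratio) is the total; subtracting the variance explained by the primary,
    slope^2 * var(log primary), leaves the residual.
    """
    _, sigma_total = lognormal_from_quantiles(E1_POSITIVE_SUV_SPEC)
    _, sigma_primary = lognormal_from_quantiles(PRIMARY_SUV_SPEC)
    return math.sqrt(max(sigma_total**2 - slope**2 * sigma_primary**2, 0.0))


@dataclass
class CohortConfig:
    """All generative parameters of a synthetic cohort.

    Defaults reproduce the published cohort margins: 180 patients, mean
    node counts 169/180, 297/180, 209/180 per echelon, involvement
    prevalences 0.86/0.42/0.096, node flag rates from the 675-node table,
    and log-normal parameters derived from published quantiles.  Derived
    fields left as ``None`` are filled in ``__post_init__``.
    """

    n_patients: int = 180
    mean_nodes_per_echelon: tuple[float, float, float] = (169 / 180, 297 / 180, 209 / 180)
    prevalence_by_echelon: tuple[float, float, float] = (0.86, 0.42, 0.096)
    ebus_sensitivity: float = 1.0
    primary_suv_lognormal: Optional[tuple[float, float]] = None
    positive_slope: float = 0.55
    positive_intercept: Optional[float] = None
    echelon_offsets: tuple[float, float] = (-0.328, -0.422)  # echelon-2, -3 vs -1
    sigma_res: Optional[float] = None
    negative_node_lognormal: Optional[tuple[float, float]] = None
    diameter_lognormal: Optional[dict[tuple[int, int], tuple[float, float]]] = None
    p_conglomerate: float = 0.03
    p_adeno: float = 304 / 675
    p_right_primary: float = 337 / 675
    p_station4R_given_left: float = 55 / 338
    target_median_suv_e1_positive: float = 10.6
    seed: int = 0

    def __post_init__(self):
        if self.primary_suv_lognormal is None:
            self.primary_suv_lognormal = lognormal_from_quantiles(PRIMARY_SUV_SPEC)
        if self.negative_node_lognormal is None:
            self.negative_node_lognormal = lognormal_from_quantiles(NEGATIVE_SUV_SPEC)
        if self.sigma_res is None:
            self.sigma_res = _default_sigma_res(self.positive_slope)
        if self.positive_intercept is None:
            self.positive_intercept = calibrate_positive_intercept(
                self.positive_slope,
                self.primary_suv_lognormal[0],
                self.target_median_suv_e1_positive,
            )
        if self.diameter_lognormal is None:
            self.diameter_lognormal = {
                key: lognormal_from_quantiles(spec)
                for key, spec in DIAMETER_SPECS.items()
            }
        self.validate()

    def validate(self) -> None:
        probs = [
            self.ebus_sensitivity, self.p_conglomerate, self.p_adeno,
            self.p_right_primary, self.p_station4R_given_left,
            *self.prevalence_by_echelon,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if any(m <= 0 for m in self.mean_nodes_per_echelon):
            raise ValueError("mean node counts must be positive")
        if self.sigma_res < 0 or self.primary_suv_lognormal[1] < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _truncated_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                         lower: float, size: int = 1) -> np.ndarray:
    """Draw from a log-normal conditioned on exceeding ``lower``."""
    if sigma == 0.0:
        return np.full(size, max(math.exp(mu), lower))
    a = stats.norm.cdf((math.log(lower) - mu) / sigma)
    u = a + (1.0 - a) * rng.random(size)
    # guard against u == 1 rounding
    u = np.clip(u, a, 1.0 - 1e-12)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _draw_diameter(rng, config, echelon, status, conglomerate) -> float:
    mu, sigma = config.diameter_lognormal[(echelon, status)]
    lower = CONGLOMERATE_MIN_DIAMETER_CM if conglomerate else MIN_NODE_DIAMETER_CM
    return float(_truncated_lognormal(rng, mu, sigma, lower, 1)[0])


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one synthetic cohort; bit-identical under a fixed seed."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    patient_seeds = root.spawn(config.n_patients)
    mu_p, sigma_p = config.primary_suv_lognormal
    mu_n, sigma_n = config.negative_node_lognormal
    records: list[LymphNodeRecord] = []

    for p_idx in range(config.n_patients):
        rng = np.random.default_rng(patient_seeds[p_idx])
        pid = f"P{p_idx + 1:04d}"
        primary_suv = float(np.exp(mu_p + sigma_p * rng.standard_normal()))
        right_sided = int(rng.random() < config.p_right_primary)
        adeno = int(rng.random() < config.p_adeno)
        counts = rng.poisson(config.mean_nodes_per_echelon)
        if counts.sum() == 0:  # redraw once, then accept whatever comes
            counts = rng.poisson(config.mean_nodes_per_echelon)

        patient_nodes = []  # (echelon, truth, suv, diameter, conglomerate, st4R, ebus)
        for echelon in (1, 2, 3):
            delta = 0.0 if echelon == 1 else config.echelon_offsets[echelon - 2]
            for _ in range(int(counts[echelon - 1])):
                truth = int(rng.random() < config.prevalence_by_echelon[echelon - 1])
                if truth:
                    log_suv = (
                        config.positive_intercept
                        + config.positive_slope * math.log(primary_suv)
                        + delta
                        + config.sigma_res * rng.standard_normal()
                    )
                    suv = math.exp(log_suv)
                else:
                    suv = float(np.exp(mu_n + sigma_n * rng.standard_normal()))
                suv = max(suv, 1e-6)
                conglomerate = int(rng.random() < config.p_conglomerate)
                diameter = _draw_diameter(rng, config, echelon, truth, conglomerate)
                st4r = 0
                if not right_sided:
                    st4r = int(rng.random() < config.p_station4R_given_left)
                ebus = truth * int(rng.random() < config.ebus_sensitivity)
                patient_nodes.append((echelon, truth, suv, diameter, conglomerate, st4r, ebus))

        e2_suvs = [n[2] for n in patient_nodes if n[0] == 2]
        if e2_suvs:
            largest_e2 = max(e2_suvs)
        else:
            # auxiliary draw: an unsampled background echelon-2 node
            largest_e2 = float(np.exp(mu_n + sigma_n * rng.standard_normal()))

        for echelon, truth, suv, diameter, conglomerate, st4r, ebus in patient_nodes:
            records.append(
                LymphNodeRecord(
                    patient_id=pid,
                    echelon=echelon,
                    suv_max=suv,
                    suv_max_primary=primary_suv,
                    short_diameter_cm=diameter,
                    conglomerate=conglomerate,
                    station4R_left_primary=st4r,
                    histology_adeno=adeno,
                    primary_right_sided=right_sided,
                    largest_suv_echelon2=largest_e2,
                    ebus_positive=ebus,
                    truth_positive=truth,
                )
            )

    return Cohort(records=tuple(records),
                  provenance=f"synthetic:{config.config_hash()}:seed={config.seed}")
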