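"""Closed-form combination of two diagnostic tests and expected errors.

A combined (parallel, "believe the positive") test calls a node positive
when either component test is positive.  Under independence of the test
results,

    SE_ab = SE_a + SE_b - SE_a * SE_b      (sensitivity rises)
    SP_ab = SP_a * SP_b                    (specificity falls)

The expected-error arithmetic back-calculates the prevalence of truly
involved nodes from the observed positive count and an assumed reference
sensitivity (EBUS-TBNA at 85% when its specificity is taken as 100%),
then converts a combined sensitivity and a called-positive count into
expected false negatives, false positives and misclassifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TestCharacteristics",
    "CombinedTestResult",
    "combined_sensitivity",
    "combined_specificity",
    "prevalence_from_positives",
    "expected_errors",
    "combine_calls",
]


@dataclass(frozen=True)
class TestCharacteristics:
    sensitivity: float
    specificity: float

    def __post_init__(self):
        for v in (self.sensitivity, self.specificity):
            if not (0.0 <= v <= 1.0):
                raise ValueError("sensitivity/specificity must be in [0, 1]")


@dataclass(frozen=True)
class CombinedTestResult:
    """Expected error bookkeeping of a combined test at a prevalence."""

    sensitivity: float
    prevalence: float
    n_called_positive: float
    expected_fn: float
    expected_tp: float
    expected_fp: float
    expected_misclassifications: float
    fp_floored: bool = False


def _check_prob(*values):
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"probability {v} outside [0, 1]")


def combined_sensitivity(se_a: float, se_b: float) -> float:
    """SE_ab = SE_a + SE_b - SE_a * SE_b (independence)."""
    _check_prob(se_a, se_b)
    return se_a + se_b - se_a * se_b


def combined_specificity(sp_a: float, sp_b: float) -> float:
    """SP_ab = SP_a * SP_b (independence)."""
    _check_prob(sp_a, sp_b)
    return sp_a * sp_b


def prevalence_from_positives(n_observed_positive: float,
                              assumed_sensitivity: float) -> float:
    """Back-calculated count of truly involved nodes.

    With a reference test of perfect specificity and sensitivity s, the
    n observed positives are s of the truly involved, so the prevalence
    is n / s (e.g. 291 observed positives at s = 0.85 -> 342.35,
    conventionally rounded to 342).
    """
    if assumed_sensitivity <= 0:
        raise ValueError("assumed sensitivity must be > 0")
    if n_observed_positive < 0:
        raise ValueError("positive count must be >= 0")
    return n_observed_positive / assumed_sensitivity


def expected_errors(prevalence: float, sensitivity: float,
                    n_called_positive: float) -> CombinedTestResult:
    """Expected false negatives/positives and misclassifications.

    expected_fn = prevalence * (1 - sensitivity);
    expected_tp = prevalence - expected_fn;
    expected_fp = n_called_positive - expected_tp (floored at 0 with an
    inconsistency flag); misclassifications = expected_fp + expected_fn.
    """
    if prevalence <= 0:
        raise ValueError("prevalence must be > 0")
    _check_prob(sensitivity)
    expected_fn = prevalence * (1.0 - sensitivity)
    expected_tp = prevalence - expected_fn
    raw_fp = n_called_positive - expected_tp
    fp_floored = raw_fp < 0
    expected_fp = max(raw_fp, 0.0)
    return CombinedTestResult(
        sensitivity=sensitivity,
        prevalence=prevalence,
        n_called_positive=n_called_positive,
        expected_fn=expected_fn,
        expected_tp=expected_tp,
        expected_fp=expected_fp,
        expected_misclassifications=expected_fp + expected_fn,
        fp_floored=fp_floored,
    )


def combine_calls(calls_a, calls_b) -> np.ndarray:
    """Element-wise OR of two binary call vectors."""
    a = np.asarray(calls_a, int)
    b = np.asarray(calls_b, int)
    if a.shape != b.shape:
        raise ValueError("call vectors must have equal length")
    return ((a == 1) | (b == 1)).astype(int)
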