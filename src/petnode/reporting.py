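"""End-to-end experiment driver.

``run_experiment`` generates (or loads) a node-level cohort, computes
cross-validated scores for the configured classifiers, calibrates each to
the configured target sensitivities, and writes a report bundle:

* a classifier-performance table (classifier x target sensitivity with
  MCR, false negatives, and weighted exact McNemar p-values against a
  reference classifier),
* a per-echelon table (misclassification error rate, false negatives,
  FDR, including OR-combined test rows),
* a combined-test analytic report at the back-calculated prevalence,
* ECDF coordinate tables for SUVmax and short-axis diameter by
  echelon x EBUS status.

The reference classifier for the McNemar comparisons is a
"pseudo-expert": the fixed SUVmax-threshold classifier calibrated to
94.5% sensitivity against the latent truth — a synthetic stand-in for
the human expert rater that a real dataset would provide; it is labelled
as such in every output.  All outputs carry the seed and a config hash.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import Cohort, load_cohort
from .synthetic import CohortConfig, generate_cohort
from .classifiers import (
    design_matrix,
    fit_probabilistic_backend,
    logistic_trainer,
    make_weights,
)
from .calibration import (
    CalibrationError,
    assign_folds,
    cutoff_for_sensitivity,
    cv_scores,
    nested_cv_scores,
    weight_for_sensitivity,
)
from .evalstats import confusion, metrics, mcnemar_exact_weighted
from .combined import (
    combined_sensitivity,
    expected_errors,
    prevalence_from_positives,
)

__all__ = ["ExperimentConfig", "run_experiment", "fixed_threshold_classifier"]

CLASSIFIER_KINDS = ("logistic", "tree_ensemble", "feedforward", "fixed_suv_threshold")

#: Reference sensitivity of the pseudo-expert rater stand-in.
PSEUDO_EXPERT_SENSITIVITY = 0.945


@dataclass
class ExperimentConfig:
    """Driver configuration; at least one classifier and one target."""

    cohort: Optional[CohortConfig] = None
    cohort_path: Optional[str] = None
    classifiers: tuple[str, ...] = ("logistic", "fixed_suv_threshold")
    target_sensitivities: tuple[float, ...] = (0.945, 0.979, 0.993)
    fixed_suv_threshold: float = 2.5
    mcnemar_weights: tuple[float, ...] = (1.0, 9.0, 20.0)
    weight_grid: tuple[float, ...] = tuple(range(1, 21))
    ebus_assumed_sensitivity: float = 0.85
    k_outer: int = 3
    m_inner: int = 5
    seed: int = 0
    output_dir: str = "petnode_report"

    def __post_init__(self):
        if not self.classifiers:
            raise ValueError("need at least one classifier")
        if not self.target_sensitivities:
            raise ValueError("need at least one target sensitivity")
        for kind in self.classifiers:
            if kind not in CLASSIFIER_KINDS:
                raise ValueError(f"unknown classifier kind {kind!r}")
        if self.cohort is None and self.cohort_path is None:
            self.cohort = CohortConfig(seed=self.seed)

    def config_hash(self) -> str:
        """Hash of the semantic fields (the output directory is excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        blob = repr(sorted(payload.items(), key=lambda kv: kv[0])).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def fixed_threshold_classifier(threshold: float):
    """Scorer calling a node positive when its SUVmax is at or above the
    threshold (binary score 1/0)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")

    def scorer(suv_values) -> np.ndarray:
        suv = np.atleast_1d(np.asarray(suv_values, float))
        return (suv >= threshold).astype(float)

    return scorer


_logistic_trainer = logistic_trainer


def _backend_trainer(kind: str, weight: float, seed: int):
    def train(X, y):
        cw = make_weights(y, weight) if weight != 1 else None
        scorer = fit_probabilistic_backend(kind, X, y, weights=cw, seed=seed)
        return lambda Xt: np.atleast_1d(scorer(Xt))
    return train


def _classifier_cv_scores(kind, weight, X, y, assignment, seed):
    if kind == "logistic":
        return cv_scores(_logistic_trainer(weight), X, y, assignment)
    if kind == "tree_ensemble":
        return cv_scores(_backend_trainer(kind, weight, seed), X, y, assignment)
    if kind == "feedforward":
        return nested_cv_scores(_backend_trainer(kind, weight, seed), X, y, assignment)
    raise ValueError(kind)


def _per_echelon_rows(label, echelons, y, calls):
    rows = []
    for e in (1, 2, 3):
        mask = echelons == e
        if not mask.any():
            continue
        c = confusion(y[mask], calls[mask])
        m = metrics(c)
        rows.append({
            "classifier": label, "echelon": e, "n": int(mask.sum()),
            "n_ebus_positive": int(y[mask].sum()),
            "mer": m.mcr, "false_negatives": int(c.fn), "fdr": m.fdr,
        })
    return rows


def run_experiment(config: ExperimentConfig) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle.

    Returns a mapping of artefact names to paths.  Any stage failure
    aborts with a stage-named error and removes partial outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")

    def write_csv(frame: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        frame.insert(0, "config_hash", config.config_hash())
        frame.insert(0, "seed", config.seed)
        frame.to_csv(path, index=False)
        written.append(path)
        return path

    try:
        return _run(config, outdir, written, log, write_csv, log_lines)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"experiment failed: {exc}") from exc


def _run(config, outdir, written, log, write_csv, log_lines):
    log(f"start seed={config.seed} config_hash={config.config_hash()}")

    # --- stage: cohort -----------------------------------------------------
    if config.cohort_path is not None:
        cohort = load_cohort(config.cohort_path)
        log(f"cohort loaded from {config.cohort_path}: {len(cohort)} nodes")
    else:
        cohort = generate_cohort(config.cohort)
        log(f"cohort generated: {len(cohort)} nodes, provenance {cohort.provenance}")

    X = design_matrix(cohort)
    y = cohort.labels()
    suv = np.array([r.suv_max for r in cohort])
    echelons = np.array([r.echelon for r in cohort])
    assignment = assign_folds(len(y), config.k_outer, config.m_inner, config.seed)
    min_target = min(config.target_sensitivities)

    # --- stage: reference (pseudo-expert) ---------------------------------
    truth = cohort.labels(use_truth=True) if cohort.has_truth else y
    ref_cut = cutoff_for_sensitivity(suv, truth, PSEUDO_EXPERT_SENSITIVITY)
    ref_calls = (suv >= ref_cut).astype(int)
    log(f"pseudo_expert: SUV cutoff {ref_cut:.4g} for sensitivity "
        f"{PSEUDO_EXPERT_SENSITIVITY} on truth")

    # --- stage: classifiers -----------------------------------------------
    table4_rows = []
    table5_rows = []
    combined_rows = []
    calls_at_min_target: dict[str, np.ndarray] = {}
    sens_at_min_target: dict[str, float] = {}

    for kind in config.classifiers:
        if kind == "fixed_suv_threshold":
            calls = (suv >= config.fixed_suv_threshold).astype(int)
            c = confusion(y, calls)
            m = metrics(c)
            row = {
                "classifier": kind, "target_sensitivity": np.nan,
                "positive_weight": np.nan,
                "cutoff": config.fixed_suv_threshold,
                "achieved_sensitivity": m.sensitivity, "mcr": m.mcr,
                "false_negatives": int(c.fn),
            }
            for w in config.mcnemar_weights:
                res = mcnemar_exact_weighted(calls, ref_calls, y, w)
                row[f"mcnemar_p_w{w:g}"] = res.p_value
            table4_rows.append(row)
            table5_rows.extend(_per_echelon_rows(kind, echelons, y, calls))
            calls_at_min_target[kind] = calls
            sens_at_min_target[kind] = m.sensitivity
            log(f"{kind}: native operating point at SUV >= "
                f"{config.fixed_suv_threshold}, sensitivity {m.sensitivity:.4f}")
            continue

        # weight calibration (cut-off fixed at 0.5) for weight-capable kinds
        weight = 1.0
        if kind in ("logistic", "feedforward"):
            def trainer(w, _kind=kind):
                return cv_scores(
                    _logistic_trainer(w) if _kind == "logistic"
                    else _backend_trainer(_kind, w, config.seed),
                    X, y, assignment)
            try:
                op = weight_for_sensitivity(trainer, y, min_target,
                                            cutoff=0.5,
                                            weight_grid=config.weight_grid)
                weight = op.positive_weight
                log(f"{kind}: weight {weight:g} reaches sensitivity "
                    f"{op.achieved_sensitivity:.4f} >= {min_target} at cutoff 0.5")
            except CalibrationError as exc:
                log(f"{kind}: weight calibration failed "
                    f"(best {exc.best_achieved:.4f}); falling back to cutoff-only")
        else:
            log(f"{kind}: weight calibration unsupported, cutoff-only")

        scores = _classifier_cv_scores(kind, weight, X, y, assignment, config.seed)

        for target in sorted(config.target_sensitivities):
            cut = cutoff_for_sensitivity(scores, y, target)
            calls = (scores >= cut).astype(int)
            c = confusion(y, calls)
            m = metrics(c)
            log(f"{kind}: target {target} -> cutoff {cut:.4g}, "
                f"sensitivity {m.sensitivity:.4f}, MCR {m.mcr:.4f}")
            row = {
                "classifier": kind, "target_sensitivity": target,
                "positive_weight": weight, "cutoff": cut,
                "achieved_sensitivity": m.sensitivity, "mcr": m.mcr,
                "false_negatives": int(c.fn),
            }
            for w in config.mcnemar_weights:
                res = mcnemar_exact_weighted(calls, ref_calls, y, w)
                row[f"mcnemar_p_w{w:g}"] = res.p_value
            table4_rows.append(row)
            label = f"{kind}@{target:g}"
            table5_rows.extend(_per_echelon_rows(label, echelons, y, calls))
            if target == min_target:
                calls_at_min_target[kind] = calls
                sens_at_min_target[kind] = m.sensitivity

    # --- stage: OR-combined rows ------------------------------------------
    combinable = [k for k in calls_at_min_target if k != "fixed_suv_threshold"]
    for i, ka in enumerate(combinable):
        for kb in combinable[i + 1:]:
            calls = ((calls_at_min_target[ka] == 1)
                     | (calls_at_min_target[kb] == 1)).astype(int)
            label = f"combined:{ka}|{kb}@{min_target:g}"
            table5_rows.extend(_per_echelon_rows(label, echelons, y, calls))
    for ka in combinable:
        calls = ((calls_at_min_target[ka] == 1) | (ref_calls == 1)).astype(int)
        label = f"combined:{ka}|pseudo_expert@{min_target:g}"
        table5_rows.extend(_per_echelon_rows(label, echelons, y, calls))

    # --- stage: combined-test analytics ------------------------------------
    n_pos = int(y.sum())
    prevalence = prevalence_from_positives(n_pos, config.ebus_assumed_sensitivity)
    for kind, sens in sens_at_min_target.items():
        se_ab = combined_sensitivity(sens, config.ebus_assumed_sensitivity)
        n_called = int(calls_at_min_target[kind].sum())
        res = expected_errors(prevalence, se_ab, n_called)
        combined_rows.append({
            "classifier": kind,
            "classifier_sensitivity": sens,
            "ebus_assumed_sensitivity": config.ebus_assumed_sensitivity,
            "combined_sensitivity": se_ab,
            "prevalence": prevalence,
            "n_called_positive": n_called,
            "expected_fn": res.expected_fn,
            "expected_fp": res.expected_fp,
            "expected_misclassifications": res.expected_misclassifications,
        })
    log(f"combined-test analytics at prevalence {prevalence:.2f} "
        f"({n_pos} observed positives / {config.ebus_assumed_sensitivity})")

    # --- stage: ECDF coordinate tables -------------------------------------
    ecdf_rows = {"suv_max": [], "short_diameter_cm": []}
    values = {"suv_max": suv,
              "short_diameter_cm": np.array([r.short_diameter_cm for r in cohort])}
    for var, vals in values.items():
        for e in (1, 2, 3):
            for status in (0, 1):
                mask = (echelons == e) & (y == status)
                sub = np.sort(vals[mask])
                if sub.size == 0:
                    continue
                ecdf = np.arange(1, sub.size + 1) / sub.size
                for v, f in zip(sub, ecdf):
                    ecdf_rows[var].append(
                        {"echelon": e, "ebus_positive": status,
                         "value": v, "ecdf": f})

    # --- stage: write bundle ------------------------------------------------
    paths = {
        "table4": write_csv(pd.DataFrame(table4_rows), "classifier_performance.csv"),
        "table5": write_csv(pd.DataFrame(table5_rows), "per_echelon.csv"),
        "combined": write_csv(pd.DataFrame(combined_rows), "combined_test.csv"),
        "ecdf_suv": write_csv(pd.DataFrame(ecdf_rows["suv_max"]), "ecdf_suv.csv"),
        "ecdf_diameter": write_csv(
            pd.DataFrame(ecdf_rows["short_diameter_cm"]), "ecdf_diameter.csv"),
    }
    log("done")
    log_path = outdir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    written.append(log_path)
    paths["log"] = log_path
    return paths
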