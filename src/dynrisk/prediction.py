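"""Dynamic risk prediction and method evaluation.

Turns fitted models into per-subject conditional event probabilities at
a horizon given biomarker history up to a landmark time, and scores them
with AUROC (Mann-Whitney estimator, DeLong variance, normal 95% CI —
the pROC-style default) plus paired Wilcoxon method comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .baselines import build_landmark_data, fit_cox_last_value, fit_pccox
from .datasets import LongitudinalDataset
from .joint import JointModelFit, fit_joint_model, posterior_risk
from .latent_class import JLCMFit, class_risk_score, select_ng
from .simulate import truncate_followup

__all__ = [
    "RiskPrediction",
    "EvaluationResult",
    "predict_dynamic_risk",
    "auroc",
    "evaluate_scenario",
    "compare_methods",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("jm", "lcmm", "pccox", "cox")

DEFAULT_FOLLOWUPS = (5.0, 10.0, 15.0)
DEFAULT_HORIZON = 20.0


@dataclass
class RiskPrediction:
    subject_id: object
    s: float                    # years of history used
    t: float                    # horizon
    risk: float                 # P(event by t | history to s, event-free at s)
    method: str = "jm"

    def __post_init__(self):
        if self.t < self.s:
            raise ValueError("horizon t must be >= history time s")
        if not (0.0 <= self.risk <= 1.0):
            raise ValueError("risk must be a probability")


@dataclass
class EvaluationResult:
    method: str
    scenario_id: str
    followup_length: float
    auroc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    converged: bool = True
    reason: str = ""


def predict_dynamic_risk(
    fit: JointModelFit,
    subject_id,
    times,
    values,
    s: float,
    t: float,
    condition_on_survival: bool = True,
) -> RiskPrediction:
    """Conditional event risk by ``t`` for a subject event-free at ``s``.

    A subject with no measurements falls back to the population risk
    (prior over the random effects) with a warning.
    """
    times = np.asarray(times, float)
    if times.size == 0:
        logger.warning("subject %s has no measurements by s=%s; using population risk",
                       subject_id, s)
    risk = posterior_risk(fit, times, values, s, t,
                          condition_on_survival=condition_on_survival)
    return RiskPrediction(subject_id=subject_id, s=s, t=t, risk=risk)


# ---------------------------------------------------------------------------
# AUROC with DeLong variance
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auroc(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """Mann-Whitney AUROC with a DeLong normal-approximation CI.

    ``labels`` are 0/1 (1 = case); scores are event risks and are NOT
    auto-oriented: estimates below 0.5 are reported as computed.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    r_pos = _midranks(pos)
    r_neg = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[:m] - r_pos) / n
    v01 = 1.0 - (all_ranks[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


# ---------------------------------------------------------------------------
# scenario evaluation
# ---------------------------------------------------------------------------

def _subject_histories(data: LongitudinalDataset, s: float):
    """(sid, times<=s, values, label) per subject; empty histories kept."""
    meas = data.measurements.sort_values(["subject_id", "time"])
    grouped = {sid: df for sid, df in meas.groupby("subject_id", sort=False)}
    out = []
    for _, row in data.subjects.iterrows():
        sid = row["subject_id"]
        df = grouped.get(sid)
        if df is None:
            t = np.array([])
            v = np.array([])
        else:
            keep = df["time"].to_numpy() <= s + 1e-12
            t = df["time"].to_numpy()[keep]
            v = df["value"].to_numpy()[keep]
        out.append((sid, t, v, int(row["status"])))
    return out


def fit_method(method: str, train: LongitudinalDataset, seed: int = 0, **kwargs):
    """Fit one of the comparator methods on full training data."""
    if method == "jm":
        return fit_joint_model(train, **kwargs)
    if method == "lcmm":
        return select_ng(train, candidates=(1, 2),
                         n_starts=kwargs.pop("n_starts", 5), seed=seed, **kwargs)
    if method == "pccox":
        landmarks = kwargs.pop("landmarks", list(DEFAULT_FOLLOWUPS))
        lm = build_landmark_data(train, landmarks=landmarks)
        return fit_pccox(lm)
    if method == "cox":
        return fit_cox_last_value(train)
    raise ValueError(f"unknown method {method!r}")


def score_subjects(method: str, fit, test: LongitudinalDataset, s: float, t: float):
    """Risk scores and labels for test subjects using history up to ``s``."""
    hist = _subject_histories(test, s)
    scores, labels = [], []
    for sid, times, values, label in hist:
        if method == "jm":
            risk = posterior_risk(fit, times, values, s, t)
        elif method == "lcmm":
            risk = class_risk_score(fit, times, values, s, t)
        elif method in ("pccox", "cox"):
            if len(values) == 0:
                continue  # flagged upstream; no marker available
            risk = float(fit.risk_score(values[-1]))
        else:
            raise ValueError(f"unknown method {method!r}")
        scores.append(risk)
        labels.append(label)
    return np.asarray(scores, float), np.asarray(labels, int)


def evaluate_scenario(
    train_data: LongitudinalDataset,
    test_data: LongitudinalDataset,
    methods=METHODS,
    followups=DEFAULT_FOLLOWUPS,
    horizon: float = DEFAULT_HORIZON,
    scenario_id: str = "",
    seed: int = 0,
) -> list[EvaluationResult]:
    """Fit each method on the training set, score truncated test histories.

    One result row per (method, follow-up length); method failures and
    non-convergence produce rows with NaN AUROC and a reason code rather
    than aborting the evaluation.
    """
    if not scenario_id and "config" in train_data.truth:
        scenario_id = train_data.truth["config"].scenario_id
    results = []
    for method in methods:
        try:
            fit = fit_method(method, train_data, seed=seed)
            fit_ok = getattr(fit, "converged", True)
            reason = "" if fit_ok else "non-convergence"
        except Exception as exc:  # single-method failure is reportable data
            fit, fit_ok, reason = None, False, f"fit error: {exc}"
            logger.warning("scenario %s method %s failed: %s", scenario_id, method, exc)
        for s in followups:
            if fit is None or not fit_ok:
                results.append(EvaluationResult(
                    method, scenario_id, s, np.nan, np.nan, np.nan, 0, 0,
                    converged=False, reason=reason or "non-convergence"))
                continue
            test_s = truncate_followup(test_data, s)
            flagged = set(test_s.truth.get("flagged_empty", []))
            keep = ~test_s.subjects["subject_id"].isin(flagged)
            test_kept = LongitudinalDataset(
                test_s.measurements, test_s.subjects[keep], test_s.features)
            scores, labels = score_subjects(method, fit, test_kept, s, horizon)
            try:
                est, lo, hi = auroc(scores, labels)
            except ValueError as exc:
                results.append(EvaluationResult(
                    method, scenario_id, s, np.nan, np.nan, np.nan,
                    int(labels.sum()), int((1 - labels).sum()),
                    converged=True, reason=str(exc)))
                continue
            results.append(EvaluationResult(
                method, scenario_id, s, est, lo, hi,
                int(labels.sum()), int((1 - labels).sum()),
                converged=True, reason=""))
    return results


def compare_methods(results_a, results_b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value over scenario AUROCs.

    Zero differences are dropped; exact distribution for n <= 25 without
    ties, normal approximation with continuity correction otherwise.
    """
    a = np.asarray(results_a, float)
    b = np.asarray(results_b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    n = len(d)
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                         method=method if method == "exact" else "approx")
    return float(res.pvalue)
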