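"""Non-joint comparator models.

* Partly conditional Cox (PCCox): the marker history is summarized at a
  grid of landmark times; all (subject, landmark) rows where the subject
  is still at risk are stacked and a Cox model is fitted on residual
  time with subject-clustered robust variance.
* Conventional last-value Cox: a single Cox fit using each subject's
  last observed abundance.

Cox partial-likelihood maximization is delegated to lifelines
(Efron tie handling, sandwich variance); this module owns the landmark
data construction and the separation/degeneracy handling around it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .datasets import LongitudinalDataset
from .lmm import LMMFit, predict_blup

__all__ = [
    "CoxFit",
    "build_landmark_data",
    "fit_pccox",
    "fit_cox_last_value",
    "last_values",
]

logger = logging.getLogger(__name__)

LANDMARK_COLUMNS = ["subject_id", "landmark_s", "marker_value", "residual_time", "event_indicator"]

#: hard cap on |log hazard ratio| used when the likelihood is monotone
BETA_CAP = 50.0


@dataclass
class CoxFit:
    beta_hat: float             # log hazard ratio per abundance unit
    se: float
    loglik: float               # partial log-likelihood at the fit
    p: float
    z: float
    converged: bool
    message: str = ""

    def risk_score(self, marker_value):
        """Linear predictor; monotone in marker_value for beta_hat > 0."""
        return self.beta_hat * np.asarray(marker_value, float)


def last_values(data: LongitudinalDataset) -> pd.DataFrame:
    """Per-subject last observed (time, value), merged with survival info."""
    meas = data.measurements.sort_values(["subject_id", "time"])
    last = meas.groupby("subject_id", sort=False).tail(1)
    return last.merge(data.subjects, on="subject_id", how="inner")


def build_landmark_data(
    data: LongitudinalDataset,
    landmarks: list[float],
    summary: str = "last_value",
    lmm_fit: LMMFit | None = None,
) -> pd.DataFrame:
    """Stacked landmark table for partly conditional Cox regression.

    At each landmark ``s``, subjects still at risk (``event_time > s``)
    contribute one row with the marker summarized from measurements at
    times <= s — either the last observed value (default) or the
    model-implied current value from LMM empirical-Bayes estimates
    (``summary="blup"``, requires ``lmm_fit``).
    """
    if summary not in ("last_value", "blup"):
        raise ValueError(f"unknown marker summary {summary!r}")
    if summary == "blup" and lmm_fit is None:
        raise ValueError("summary='blup' requires lmm_fit")
    meas = data.measurements.sort_values(["subject_id", "time"])
    rows = []
    n_dropped = 0
    for _, subj in data.subjects.iterrows():
        sid = subj["subject_id"]
        sub = meas[meas["subject_id"] == sid]
        for s in landmarks:
            if subj["event_time"] <= s:
                continue  # not at risk at this landmark
            hist = sub[sub["time"] <= s + 1e-12]
            if hist.empty:
                n_dropped += 1
                continue
            if summary == "last_value":
                value = float(hist["value"].iloc[-1])
            else:
                b0, b1 = predict_blup(
                    lmm_fit, hist["time"].to_numpy(), hist["value"].to_numpy()
                )
                value = float(
                    lmm_fit.beta[0] + b0 + (lmm_fit.beta[1] + b1) * s
                )
            rows.append(
                (sid, s, value, subj["event_time"] - s, int(subj["status"]))
            )
    if n_dropped:
        logger.warning("build_landmark_data: dropped %d (subject, landmark) rows "
                       "without pre-landmark measurements", n_dropped)
    return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


def _fit_cox_breslow(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxFit:
    """Newton fit of the 1-covariate Cox partial likelihood, Breslow ties."""
    x = df["marker_value"].to_numpy(float)
    T = df[duration_col].to_numpy(float)
    d = df[event_col].to_numpy(int)
    beta = 0.0
    for _ in range(50):
        eta = np.exp(np.clip(beta * x, -700, 700))
        ll = g = h = 0.0
        for i in np.where(d == 1)[0]:
            at_risk = T >= T[i]
            s0 = eta[at_risk].sum()
            s1 = (eta[at_risk] * x[at_risk]).sum()
            s2 = (eta[at_risk] * x[at_risk] ** 2).sum()
            ll += beta * x[i] - np.log(s0)
            g += x[i] - s1 / s0
            h += s2 / s0 - (s1 / s0) ** 2
        if h <= 0:
            break
        step = g / h
        beta += np.clip(step, -5, 5)
        if abs(step) < 1e-10:
            break
    beta = float(np.clip(beta, -BETA_CAP, BETA_CAP))
    se = float(1 / np.sqrt(h)) if h > 0 else np.nan
    z = beta / se if np.isfinite(se) else np.nan
    from scipy import stats

    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return CoxFit(beta_hat=beta, se=se, loglik=float(ll), p=p, z=float(z),
                  converged=True, message="breslow ties")


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
             cluster_col: str | None = None, ties: str = "efron") -> CoxFit:
    if df[event_col].sum() < 1:
        raise ValueError("need at least one event")
    marker = df["marker_value"]
    if np.isclose(marker.std(ddof=0), 0.0):
        return CoxFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                      "marker constant: non-identifiable")
    if ties == "breslow":
        return _fit_cox_breslow(df, duration_col, event_col)
    if ties != "efron":
        raise ValueError(f"unknown tie handling {ties!r}")
    cols = ["marker_value", duration_col, event_col] + (
        [cluster_col] if cluster_col else []
    )
    kwargs = {"duration_col": duration_col, "event_col": event_col}
    if cluster_col:
        kwargs.update(cluster_col=cluster_col, robust=True)
    cph = CoxPHFitter()
    message = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[cols], **kwargs)
    except ConvergenceError:
        # monotone likelihood (e.g. perfect separation): refit with a ridge
        cph = CoxPHFitter(penalizer=1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[cols], **kwargs)
        message = "monotone likelihood: ridge-stabilized fit"
    beta = float(cph.params_["marker_value"])
    if abs(beta) > BETA_CAP:
        beta = float(np.sign(beta) * BETA_CAP)
        message = message or "monotone likelihood: beta capped"
    summary = cph.summary.loc["marker_value"]
    return CoxFit(
        beta_hat=beta,
        se=float(summary["se(coef)"]),
        loglik=float(cph.log_likelihood_),
        p=float(summary["p"]),
        z=float(summary["z"]),
        converged=True,
        message=message,
    )


def fit_pccox(landmark_data: pd.DataFrame, ties: str = "efron") -> CoxFit:
    """Cox fit on stacked landmark rows (residual time, Efron ties by
    default, subject-clustered sandwich variance)."""
    return _fit_cox(landmark_data, "residual_time", "event_indicator",
                    cluster_col="subject_id" if ties == "efron" else None,
                    ties=ties)


def fit_cox_last_value(data: LongitudinalDataset, ties: str = "efron") -> CoxFit:
    """Conventional Cox model on each subject's last observed abundance."""
    df = last_values(data).rename(columns={"value": "marker_value"})
    if (df.groupby("subject_id").size() < 1).any():  # pragma: no cover
        raise ValueError("every subject needs at least one measurement")
    return _fit_cox(df, "event_time", "status", ties=ties)
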