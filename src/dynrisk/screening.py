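"""Per-feature screening pipeline for longitudinal biomarker panels.

The strategy: metadata prefilter (peptide support, missingness), one
model fit per feature per method with automated selection, multiplicity
control over features, AUROC-based prioritization at successive
evaluation ages, consensus across methods, and leave-one-out
cross-validation of the selected features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import build_landmark_data, fit_pccox
from .datasets import LongitudinalDataset
from .joint import fit_joint_model, wald_test
from .latent_class import class_risk_score, select_ng
from .prediction import auroc, score_subjects, _subject_histories

__all__ = [
    "ScreenConfig",
    "ScreenRow",
    "prefilter",
    "bh_adjust",
    "screen_feature",
    "screen_cohort",
    "consensus",
    "loocv_screen",
]

logger = logging.getLogger(__name__)

SCREEN_METHODS = ("jm", "lcmm", "pccox")


@dataclass(frozen=True)
class ScreenConfig:
    eval_ages: tuple = (5.0, 6.0, 7.0, 8.0)
    horizon_age: float = 13.0
    min_peptides: int = 6
    max_missing: int = 10
    auroc_threshold: float = 0.75
    auroc_last_k: int = 2
    min_per_class: int = 5
    p_thresholds: dict = field(default_factory=lambda: {"jm": 0.05, "pccox": 0.01})
    consensus_k: int = 2
    use_adjusted: bool = False
    min_class_size: int = 5         # latent-class modal-assignment constraint
    lcmm_starts: int = 5

    def __post_init__(self):
        if sorted(self.eval_ages) != list(self.eval_ages):
            raise ValueError("eval_ages must be sorted ascending")
        if self.horizon_age <= max(self.eval_ages):
            raise ValueError("horizon_age must exceed the last evaluation age")
        if not (0 < self.auroc_threshold <= 1):
            raise ValueError("auroc_threshold must be in (0, 1]")


@dataclass
class ScreenRow:
    feature_id: object
    method: str
    p: float
    p_adj: float
    auroc_by_age: dict              # age -> (auroc, ci_low, ci_high)
    passed_prefilter: bool
    passed_auroc: bool
    passed_class_size: bool
    selected: bool
    reason: str = ""
    ng: int | None = None           # latent-class fits only


def prefilter(features: pd.DataFrame, config: ScreenConfig = ScreenConfig()) -> list:
    """Feature ids passing the metadata filter (both bounds inclusive)."""
    feats = features.copy()
    missing_meta = feats["n_peptides"].isna() | feats["n_missing"].isna()
    if missing_meta.any():
        logger.warning("excluding %d feature(s) with missing metadata",
                       int(missing_meta.sum()))
        feats = feats[~missing_meta]
    keep = (feats["n_peptides"] >= config.min_peptides) & (
        feats["n_missing"] <= config.max_missing
    )
    return feats.loc[keep, "feature_id"].tolist()


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    out = np.full(m, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    k = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * k / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(k)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _class_counts_at_age(data: LongitudinalDataset, age: float) -> tuple[int, int]:
    meas = data.measurements[data.measurements["time"] <= age + 1e-12]
    with_meas = data.subjects[data.subjects["subject_id"].isin(meas["subject_id"])]
    return (
        int((with_meas["status"] == 1).sum()),
        int((with_meas["status"] == 0).sum()),
    )


def screen_feature(
    feature_data: LongitudinalDataset,
    method: str,
    config: ScreenConfig = ScreenConfig(),
    seed: int = 0,
    **fit_kwargs,
) -> ScreenRow:
    """Fit one method for one feature and assemble its screening record.

    AUROC at each evaluation age uses only measurements at ages <= that
    age to predict status at the horizon age. Non-convergence yields a
    non-selected row with a reason code.
    """
    fid = feature_data.features["feature_id"].iloc[0]
    row = ScreenRow(
        feature_id=fid, method=method, p=np.nan, p_adj=np.nan, auroc_by_age={},
        passed_prefilter=True, passed_auroc=False, passed_class_size=False,
        selected=False,
    )
    ng = None
    lcmm_ok = False
    try:
        if method == "jm":
            fit = fit_joint_model(feature_data, **fit_kwargs)
            if not fit.converged:
                row.reason = "non-convergence"
                return row
            _, row.p = wald_test(fit)
        elif method == "lcmm":
            fit = select_ng(feature_data, candidates=(1, 2),
                            n_starts=config.lcmm_starts, seed=seed, **fit_kwargs)
            if not fit.converged:
                row.reason = "non-convergence"
                return row
            ng = fit.ng
            lcmm_ok = fit.ng == 2 and fit.min_class_size_ok(config.min_class_size)
        elif method == "pccox":
            lm = build_landmark_data(feature_data, landmarks=list(config.eval_ages))
            fit = fit_pccox(lm)
            if not fit.converged:
                row.reason = fit.message or "non-convergence"
                return row
            row.p = fit.p
        else:
            raise ValueError(f"unknown screening method {method!r}")
    except Exception as exc:
        row.reason = f"fit error: {exc}"
        return row
    row.ng = ng

    # AUROC per evaluation age + class-size flags
    class_ok = []
    for age in config.eval_ages:
        n_case, n_ctrl = _class_counts_at_age(feature_data, age)
        ok = n_case >= config.min_per_class and n_ctrl >= config.min_per_class
        class_ok.append(ok)
        scores, labels = score_subjects(method, fit, feature_data, age, config.horizon_age)
        try:
            row.auroc_by_age[age] = auroc(scores, labels)
        except ValueError:
            row.auroc_by_age[age] = (np.nan, np.nan, np.nan)
    last_k_ages = config.eval_ages[-config.auroc_last_k:]
    row.passed_class_size = all(
        ok for age, ok in zip(config.eval_ages, class_ok) if age in last_k_ages
    )
    last_aucs = [row.auroc_by_age[a][0] for a in last_k_ages]
    row.passed_auroc = all(
        np.isfinite(a) and a >= config.auroc_threshold for a in last_aucs
    )

    if method == "lcmm":
        evidence = lcmm_ok
    else:
        thr = config.p_thresholds.get(method, 0.05)
        evidence = np.isfinite(row.p) and row.p < thr
    row.selected = bool(
        row.passed_prefilter and row.passed_auroc and row.passed_class_size and evidence
    )
    return row


def screen_cohort(
    data: LongitudinalDataset,
    methods=SCREEN_METHODS,
    config: ScreenConfig = ScreenConfig(),
    seed: int = 0,
    **fit_kwargs,
) -> list[ScreenRow]:
    """Run the full screen: prefilter, per-feature fits, BH adjustment.

    BH adjustment is computed per method across the prefiltered features;
    with ``config.use_adjusted`` the adjusted p drives selection for the
    p-value-based methods.
    """
    kept = prefilter(data.features, config)
    rows: list[ScreenRow] = []
    for method in methods:
        method_rows = []
        for fid in kept:
            fd = data.single_feature(fid)
            method_rows.append(
                screen_feature(fd, method, config, seed=seed, **fit_kwargs)
            )
        pvals = np.array([r.p for r in method_rows], float)
        padj = bh_adjust(pvals)
        for r, pa in zip(method_rows, padj):
            r.p_adj = float(pa) if np.isfinite(pa) else np.nan
            if config.use_adjusted and method != "lcmm":
                thr = config.p_thresholds.get(method, 0.05)
                evidence = np.isfinite(r.p_adj) and r.p_adj < thr
                r.selected = bool(
                    r.passed_prefilter and r.passed_auroc
                    and r.passed_class_size and evidence
                )
        rows.extend(method_rows)
    return rows


def consensus(rows: list[ScreenRow], consensus_k: int = 2) -> list:
    """Features selected by at least ``consensus_k`` methods."""
    methods = {r.method for r in rows}
    if len(methods) < 2:
        raise ValueError("consensus requires at least 2 screened methods")
    hits: dict = {}
    for r in rows:
        if r.selected:
            hits.setdefault(r.feature_id, set()).add(r.method)
    return sorted([fid for fid, ms in hits.items() if len(ms) >= consensus_k])


def rows_to_frame(rows: list[ScreenRow]) -> pd.DataFrame:
    """Flatten screen rows to a tidy table (one row per feature x method)."""
    recs = []
    for r in rows:
        rec = {
            "feature_id": r.feature_id, "method": r.method, "p": r.p,
            "p_adj": r.p_adj, "passed_prefilter": r.passed_prefilter,
            "passed_auroc": r.passed_auroc, "passed_class_size": r.passed_class_size,
            "selected": r.selected, "reason": r.reason, "ng": r.ng,
        }
        for age, (a, lo, hi) in r.auroc_by_age.items():
            rec[f"auroc_{age:g}"] = a
            rec[f"auroc_{age:g}_lo"] = lo
            rec[f"auroc_{age:g}_hi"] = hi
        recs.append(rec)
    return pd.DataFrame(recs)


def loocv_screen(
    data: LongitudinalDataset,
    selected_features,
    method: str,
    config: ScreenConfig = ScreenConfig(),
    seed: int = 0,
    **fit_kwargs,
) -> dict:
    """Leave-one-out cross-validated AUROC per evaluation age.

    For each left-out subject the model is refit on the remaining
    subjects (full histories) and the left-out subject's risk predicted
    at each evaluation age; pooled predictions give one AUROC per age.
    Folds whose refit fails are flagged and skipped, with the count
    reported.
    """
    selected_features = list(selected_features)
    if not selected_features:
        raise ValueError("selected features must be non-empty")
    out = {}
    for fid in selected_features:
        fd = data.single_feature(fid)
        sids = list(fd.subjects["subject_id"])
        if len(sids) < 3:
            logger.warning("LOO-CV on %d subjects is degenerate", len(sids))
        preds = {age: [] for age in config.eval_ages}
        labels = {age: [] for age in config.eval_ages}
        failed = 0
        for sid in sids:
            keep = fd.subjects["subject_id"] != sid
            train = LongitudinalDataset(
                fd.measurements[fd.measurements["subject_id"] != sid],
                fd.subjects[keep], fd.features,
            )
            held = LongitudinalDataset(
                fd.measurements[fd.measurements["subject_id"] == sid],
                fd.subjects[~keep], fd.features,
            )
            try:
                if method == "jm":
                    fit = fit_joint_model(train, **fit_kwargs)
                    ok = fit.converged
                elif method == "lcmm":
                    fit = select_ng(train, candidates=(1, 2),
                                    n_starts=config.lcmm_starts, seed=seed, **fit_kwargs)
                    ok = fit.converged
                elif method == "pccox":
                    fit = fit_pccox(build_landmark_data(train, list(config.eval_ages)))
                    ok = fit.converged
                else:
                    raise ValueError(f"unknown method {method!r}")
            except Exception as exc:
                logger.warning("LOO fold %s failed: %s", sid, exc)
                failed += 1
                continue
            if not ok:
                failed += 1
                continue
            for age in config.eval_ages:
                scores, labs = score_subjects(method, fit, held, age, config.horizon_age)
                if len(scores):
                    preds[age].append(float(scores[0]))
                    labels[age].append(int(labs[0]))
        per_age = {}
        for age in config.eval_ages:
            try:
                per_age[age] = auroc(preds[age], labels[age])
            except ValueError:
                per_age[age] = (np.nan, np.nan, np.nan)
        out[fid] = {"auroc_by_age": per_age, "n_failed_folds": failed,
                    "n_folds": len(sids)}
    return out
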