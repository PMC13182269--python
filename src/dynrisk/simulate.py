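"""Synthetic data generation.

Two generators are provided:

* :func:`simulate_dataset` — one cell of the simulation benchmark grid:
  two equal groups with opposite-sign linear abundance trends, evenly
  spaced visits, and case event times drawn from a truncated normal law
  after the follow-up window.
* :func:`simulate_cohort` — a small T1D-like screening cohort with many
  features, a planted subset of which is generated from the joint-model
  law (event hazard depends on the subject's latent trajectory through a
  known association coefficient).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` substreams, one per subject, so subject
sets are reproducible under subsetting.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ConfigurationError, LongitudinalDataset, ScenarioConfig

__all__ = [
    "DEFAULT_VARIANCE_LEVELS",
    "DEFAULT_SLOPE_LEVELS",
    "DEFAULT_GROUP_SIZES",
    "TEST_SEED_OFFSET",
    "build_scenario_grid",
    "simulate_dataset",
    "draw_case_event_times",
    "truncate_followup",
    "simulate_cohort",
    "simulate_joint_law",
]

logger = logging.getLogger(__name__)

DEFAULT_VARIANCE_LEVELS = (0.5, 1.0, 1.5)
DEFAULT_SLOPE_LEVELS = (0.0, 0.025, 0.05, 0.075, 0.1)
DEFAULT_GROUP_SIZES = (10, 50, 1000)

#: seed offset used to derive each scenario's independent test set
TEST_SEED_OFFSET = 100_000


def build_scenario_grid(
    variance_levels: Sequence[float] = DEFAULT_VARIANCE_LEVELS,
    slope_levels: Sequence[float] = DEFAULT_SLOPE_LEVELS,
    group_sizes: Sequence[int] = DEFAULT_GROUP_SIZES,
    n_visits: int = 10,
    **overrides,
) -> list[ScenarioConfig]:
    """Cartesian product of variance x slope x size, in that (outer-to-inner) order.

    The default grid yields the 45 benchmark scenarios.
    """
    if not variance_levels or not slope_levels or not group_sizes:
        raise ConfigurationError("scenario grid axes must be non-empty")
    grid = []
    for resid_sd, slope, size in itertools.product(
        variance_levels, slope_levels, group_sizes
    ):
        grid.append(
            ScenarioConfig(
                n_per_group=int(size),
                n_visits=n_visits,
                slope_coef=float(slope),
                resid_sd=float(resid_sd),
                **overrides,
            )
        )
    return grid


def visit_times(config: ScenarioConfig) -> np.ndarray:
    """Evenly spaced visit times over [0, followup_span], both ends inclusive."""
    return np.linspace(0.0, config.followup_span, config.n_visits)


def draw_case_event_times(
    n: int, config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Normal(event_mean, event_sd) truncated by rejection to (followup_span, study_end]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(config.event_mean, config.event_sd, size=2 * (n - filled))
        keep = draw[(draw > config.followup_span) & (draw <= config.study_end)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def truncated_event_mean(config: ScenarioConfig) -> float:
    """Exact mean of the truncated-normal event-time law (oracle for tests)."""
    from scipy import stats

    a = (config.followup_span - config.event_mean) / config.event_sd
    b = (config.study_end - config.event_mean) / config.event_sd
    return stats.truncnorm.mean(a, b, loc=config.event_mean, scale=config.event_sd)


def simulate_dataset(config: ScenarioConfig, seed: int | None = None) -> LongitudinalDataset:
    """Simulate one scenario dataset (single feature).

    Each subject contributes ``n_visits`` measurements at the common visit
    grid; the measured value is

        intercept_mean + b0_i + (sign_i * slope_coef) * t + eps,

    with b0_i ~ N(0, rand_int_sd^2), eps ~ N(0, resid_sd^2) and sign +1
    for cases, -1 for controls. Case event times are truncated-normal
    after follow-up; controls are censored at ``study_end``.
    """
    if seed is None:
        seed = config.seed
    times = visit_times(config)
    n = config.n_per_group
    ss = np.random.SeedSequence(seed)
    subject_streams = ss.spawn(2 * n)

    rows_subject = []
    meas_sid, meas_val = [], []
    for i in range(2 * n):
        is_case = i < n
        rng = np.random.default_rng(subject_streams[i])
        sid = f"case_{i:05d}" if is_case else f"ctrl_{i - n:05d}"
        b0 = rng.normal(0.0, config.rand_int_sd)
        sign = 1.0 if is_case else -1.0
        values = (
            config.intercept_mean
            + b0
            + sign * config.slope_coef * times
            + rng.normal(0.0, config.resid_sd, size=len(times))
        )
        if is_case:
            event_time = float(draw_case_event_times(1, config, rng)[0])
            status = 1
        else:
            event_time = config.study_end
            status = 0
        rows_subject.append((sid, event_time, status, "case" if is_case else "control"))
        meas_sid.append(np.repeat(sid, len(times)))
        meas_val.append(values)

    subjects = pd.DataFrame(
        rows_subject, columns=["subject_id", "event_time", "status", "group"]
    )
    measurements = pd.DataFrame(
        {
            "subject_id": np.concatenate(meas_sid),
            "time": np.tile(times, 2 * n),
            "feature_id": "feat_0",
            "value": np.concatenate(meas_val),
        }
    )
    features = pd.DataFrame(
        {"feature_id": ["feat_0"], "n_peptides": [10], "n_missing": [0]}
    )
    data = LongitudinalDataset(measurements, subjects, features)
    data.truth = {"config": config, "seed": seed}
    return data


def truncate_followup(data: LongitudinalDataset, horizon: float) -> LongitudinalDataset:
    """Drop measurements after ``horizon``; subjects table is untouched.

    Subjects left without any measurement are flagged in
    ``result.truth["flagged_empty"]`` and a warning is logged; downstream
    prediction excludes them.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    kept = data.measurements[data.measurements["time"] <= horizon + 1e-12]
    empty = sorted(set(data.subjects["subject_id"]) - set(kept["subject_id"]))
    if empty:
        logger.warning(
            "truncate_followup(horizon=%s): %d subject(s) left without measurements: %s",
            horizon,
            len(empty),
            empty[:5],
        )
    out = LongitudinalDataset(
        kept.reset_index(drop=True), data.subjects.copy(), data.features.copy()
    )
    out.truth = dict(data.truth)
    out.truth["flagged_empty"] = empty
    return out


def simulate_joint_law(
    theta: dict,
    n_subjects: int,
    visit_schedule: Sequence[float],
    censor_time: float,
    seed: int = 0,
) -> LongitudinalDataset:
    """Simulate directly from the shared-random-effects joint model.

    ``theta`` uses the joint-model parameter layout (beta, D, sigma2,
    log_kappa, log_lambda, alpha). Event times are drawn by inverse
    transform from the hazard
    ``kappa*lam*t^(kappa-1)*exp(alpha*(beta0+b0+(beta1+b1)t))`` and
    censored administratively at ``censor_time``; measurements keep only
    visits at or before the subject's event/censoring time (the baseline
    visit is always kept).
    """
    beta = np.asarray(theta["beta"], float)
    D = np.asarray(theta["D"], float)
    sigma2 = float(theta["sigma2"])
    kappa = float(np.exp(theta["log_kappa"]))
    lam = float(np.exp(theta["log_lambda"]))
    alpha = float(theta["alpha"])
    visit_schedule = np.asarray(sorted(visit_schedule), float)
    L = np.linalg.cholesky(D + 1e-12 * np.eye(2))

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n_subjects)
    subj_rows, meas_frames = [], []
    for i in range(n_subjects):
        rng = np.random.default_rng(streams[i])
        sid = f"subj_{i:05d}"
        b = L @ rng.standard_normal(2)
        t_event = _draw_weibull_event(
            rng, beta[0] + b[0], beta[1] + b[1], kappa, lam, alpha, t_max=censor_time
        )
        if math.isfinite(t_event):
            event_time, status, group = t_event, 1, "case"
        else:
            event_time, status, group = censor_time, 0, "control"
        t = visit_schedule[visit_schedule <= event_time + 1e-9]
        if t.size == 0:
            t = visit_schedule[:1]
        mean = beta[0] + b[0] + (beta[1] + b[1]) * t
        values = mean + rng.normal(0, math.sqrt(sigma2), size=len(t))
        subj_rows.append((sid, event_time, status, group))
        meas_frames.append(
            pd.DataFrame({"subject_id": sid, "time": t, "feature_id": "feat_0",
                          "value": values})
        )
    subjects = pd.DataFrame(
        subj_rows, columns=["subject_id", "event_time", "status", "group"]
    )
    measurements = pd.concat(meas_frames, ignore_index=True)
    features = pd.DataFrame(
        {"feature_id": ["feat_0"], "n_peptides": [10], "n_missing": [0]}
    )
    data = LongitudinalDataset(measurements, subjects, features)
    data.truth = {"theta": theta, "seed": seed}
    return data


DEFAULT_VISIT_AGES = (0.8, 2.0, 3.5, 5.0, 6.5, 8.0, 9.5, 11.0, 14.4)


def _draw_weibull_event(
    rng: np.random.Generator,
    b0: float,
    b1: float,
    kappa: float,
    lam: float,
    alpha: float,
    t_max: float,
) -> float:
    """Inverse-transform draw of T with hazard kappa*lam*t^(kappa-1)*exp(alpha*(b0+b1*t)).

    Returns +inf when the subject survives past ``t_max``.
    """
    u = rng.uniform()
    target = -math.log(u)
    # cumulative hazard on a fine grid (trapezoid); monotone -> invert
    grid = np.linspace(1e-9, t_max, 2048)
    haz = kappa * lam * grid ** (kappa - 1.0) * np.exp(alpha * (b0 + b1 * grid))
    cum = np.concatenate([[0.0], np.cumsum((haz[1:] + haz[:-1]) / 2 * np.diff(grid))])
    if target > cum[-1]:
        return math.inf
    return float(np.interp(target, cum, np.concatenate([[1e-9], grid[1:]])))


def simulate_cohort(
    n_cases: int = 11,
    n_controls: int = 10,
    n_features: int = 100,
    n_assoc: int = 5,
    onset_mean: float = 11.7,
    visit_ages: Sequence[float] = DEFAULT_VISIT_AGES,
    seed: int = 0,
    alpha: float = 2.0,
    latent_sd: tuple[float, float] = (0.5, 0.1),
    resid_sd: float = 0.3,
    intercept_mean: float = 6.0,
    weibull_shape: float = 8.0,
) -> LongitudinalDataset:
    """Simulate a small screening cohort with planted associated features.

    A latent per-subject trajectory ``m_i(t) = b0 + b1 t`` drives the
    event hazard ``kappa * lam * t^(kappa-1) * exp(alpha * m_i(t))``
    (Weibull baseline calibrated so the median onset sits near
    ``onset_mean``). Subjects are drawn from this law and assigned to the
    case pool (event before the last visit age) or control pool until both
    pools are filled, so case onset ages center near ``onset_mean``.

    The first ``n_assoc`` features are noisy readouts of the latent
    trajectory (hence genuinely associated with the hazard); the rest are
    independent noise. Planted features always pass the peptide/missing
    prefilter; null features get randomized metadata so the prefilter is
    exercised. Ground truth is stored in ``result.truth``.
    """
    if n_assoc > n_features:
        raise ConfigurationError("n_assoc must be <= n_features")
    visit_ages = np.asarray(sorted(visit_ages), dtype=float)
    censor_age = float(visit_ages[-1])
    lam = math.log(2.0) / onset_mean ** weibull_shape  # median ~ onset_mean at b=0
    ss = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])

    subjects_rows = []
    latent = {}  # sid -> (b0, b1)
    cases = controls = 0
    draw_idx = 0
    streams = list(ss.spawn(64))
    while cases < n_cases or controls < n_controls:
        if draw_idx >= len(streams):
            streams.extend(ss.spawn(64))
        rng = np.random.default_rng(streams[draw_idx])
        draw_idx += 1
        b0 = rng.normal(0.0, latent_sd[0])
        b1 = rng.normal(0.0, latent_sd[1])
        t_event = _draw_weibull_event(
            rng, b0, b1, weibull_shape, lam, alpha, t_max=censor_age
        )
        if math.isfinite(t_event):
            if cases >= n_cases:
                continue
            cases += 1
            sid = f"case_{cases:03d}"
            subjects_rows.append((sid, t_event, 1, "case"))
        else:
            if controls >= n_controls:
                continue
            controls += 1
            sid = f"ctrl_{controls:03d}"
            subjects_rows.append((sid, censor_age, 0, "control"))
        latent[sid] = (b0, b1, rng)

    subjects = pd.DataFrame(
        subjects_rows, columns=["subject_id", "event_time", "status", "group"]
    )

    feature_ids = [f"prot_{j:04d}" for j in range(n_features)]
    assoc = set(feature_ids[:n_assoc])
    meas_frames = []
    for sid, (b0, b1, rng) in latent.items():
        event_time = float(subjects.loc[subjects["subject_id"] == sid, "event_time"].iloc[0])
        t = visit_ages[visit_ages <= event_time + 1e-9]
        if len(t) == 0:
            t = visit_ages[:1]  # keep at least the first visit
        m = b0 + b1 * t
        for j, fid in enumerate(feature_ids):
            if fid in assoc:
                values = intercept_mean + m + rng.normal(0, resid_sd, size=len(t))
            else:
                f_b0 = rng.normal(0.0, latent_sd[0])
                values = intercept_mean + f_b0 + rng.normal(0, resid_sd, size=len(t))
            meas_frames.append(
                pd.DataFrame(
                    {"subject_id": sid, "time": t, "feature_id": fid, "value": values}
                )
            )
    measurements = pd.concat(meas_frames, ignore_index=True)

    n_peptides = np.where(
        np.isin(feature_ids, list(assoc)),
        meta_rng.integers(6, 25, size=n_features),
        meta_rng.integers(1, 25, size=n_features),
    )
    n_missing = np.where(
        np.isin(feature_ids, list(assoc)),
        meta_rng.integers(0, 11, size=n_features),
        meta_rng.integers(0, 20, size=n_features),
    )
    features = pd.DataFrame(
        {"feature_id": feature_ids, "n_peptides": n_peptides, "n_missing": n_missing}
    )
    data = LongitudinalDataset(measurements, subjects, features)
    data.truth = {
        "assoc_features": sorted(assoc),
        "alpha": alpha,
        "weibull_shape": weibull_shape,
        "weibull_rate": lam,
        "latent": {sid: (b0, b1) for sid, (b0, b1, _) in latent.items()},
        "seed": seed,
    }
    return data
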