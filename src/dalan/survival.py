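"""Survival-analysis primitives for patient-level image survival modelling.

This module carries the statistical core used everywhere else in the
package: the Cox negative partial log-likelihood (the training criterion),
Harrell-style concordance evaluated with the strict pairwise indicator,
Kaplan–Meier estimation, log-rank testing, and risk normalisation with
tertile stratification.

Conventions
-----------
* A subject is a :class:`SurvivalRecord` ``(time, event)`` with observed
  time ``Y = min(T, C)`` and event indicator ``delta`` (1 = event observed,
  0 = right-censored).
* Model outputs are *log-hazards*: larger values mean higher risk and hence
  shorter expected survival.
* Risk sets include tied times (``t_j >= t_i``, Breslow-style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "SurvivalRecord", "RiskPrediction", "KaplanMeierEstimate", "LogRankResult",
    "cox_partial_log_likelihood_loss", "concordance_index", "kaplan_meier",
    "logrank_test", "normalize_risks", "stratify_by_risk", "records_to_arrays",
    "RISK_GROUPS",
]

RISK_GROUPS = ("low", "mid", "high")


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's observed follow-up: time ``Y`` and event flag ``delta``."""

    time: float
    event: int

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"time must be non-negative, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass
class RiskPrediction:
    """A patient's predicted log-hazard, optionally cohort-normalised."""

    patient_id: str
    log_hazard: float
    normalized_risk: float | None = None
    risk_group: str | None = None


def records_to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray([r.time for r in records], dtype=np.float64)
    events = np.asarray([r.event for r in records], dtype=np.int64)
    return times, events


# --------------------------------------------------------------------- Cox loss
def cox_partial_log_likelihood_loss(log_hazards, records, reduction: str = "mean") -> float:
    """Negative Cox partial log-likelihood of predicted log-hazards.

    ``-sum_{i in U} [h_i - log sum_{j: t_j >= t_i} exp(h_j)]`` with ``U`` the
    event subjects.  Stabilised with a max shift inside the log-sum-exp.
    ``reduction='mean'`` divides by ``|U|`` (default); ``'sum'`` returns the
    raw sum.  An all-censored cohort contributes zero loss with a warning.
    """
    h = np.asarray(log_hazards, dtype=np.float64)
    times, events = records_to_arrays(records)
    if h.shape[0] == 0:
        raise ValueError("empty input")
    if h.shape[0] != times.shape[0]:
        raise ValueError("log_hazards and records must have equal length")
    event_idx = np.flatnonzero(events == 1)
    if event_idx.size == 0:
        warnings.warn("all subjects censored: Cox loss is 0 (no events contribute)",
                      stacklevel=2)
        return 0.0
    m = h.max()
    total = 0.0
    for i in event_idx:
        risk_set = h[times >= times[i]]
        total += h[i] - (m + np.log(np.exp(risk_set - m).sum()))
    loss = -total
    if reduction == "mean":
        loss /= event_idx.size
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return float(loss)


# ---------------------------------------------------------------------- c-index
def concordance_index(predicted_risks, records, ties: str = "strict") -> float:
    """Concordance between predicted risk ordering and observed times.

    Over admissible pairs (event subject ``i``, any ``j`` with
    ``t_j > t_i``) the pair counts as concordant when the predicted survival
    ordering agrees — i.e. the longer-lived subject has the *lower* risk.
    ``ties='strict'`` (default) scores tied predictions 0, reading the
    indicator literally; ``ties='half'`` scores them 0.5, matching the
    convention of standard survival packages.
    """
    risks = np.asarray(predicted_risks, dtype=np.float64)
    times, events = records_to_arrays(records)
    if risks.shape[0] != times.shape[0] or risks.shape[0] < 2:
        raise ValueError("need >= 2 subjects with matching risk length")
    if ties not in ("strict", "half"):
        raise ValueError(f"unknown tie convention {ties!r}")
    # pair mask: i uncensored, t_j > t_i
    later = times[None, :] > times[:, None]
    admissible = later & (events[:, None] == 1)
    n_pairs = int(admissible.sum())
    if n_pairs == 0:
        raise ValueError("no admissible pairs: need an event subject with a "
                         "longer-surviving comparator")
    concordant = admissible & (risks[None, :] < risks[:, None])
    num = float(concordant.sum())
    if ties == "half":
        num += 0.5 * float((admissible & (risks[None, :] == risks[:, None])).sum())
    return num / n_pairs


# ----------------------------------------------------------------- Kaplan–Meier
@dataclass
class KaplanMeierEstimate:
    """Product-limit survival curve with its median survival time."""

    times: np.ndarray                 # event/censor grid, ascending, starts at 0
    survival: np.ndarray              # S(t) at each grid time, right-continuous
    median: float                     # first t with S(t) <= 0.5; nan if never
    n: int = 0

    def survival_at(self, t) -> np.ndarray:
        """Evaluate the step function at arbitrary times."""
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.survival) - 1)]


def kaplan_meier(records) -> KaplanMeierEstimate:
    times, events = records_to_arrays(records)
    if times.size == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(dtype=np.float64)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=np.float64)
    med = float(kmf.median_survival_time_)   # inf when S never reaches 0.5
    return KaplanMeierEstimate(times=grid, survival=surv,
                               median=med if np.isfinite(med) else float("nan"),
                               n=int(times.size))


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    df: int


def logrank_test(groups) -> LogRankResult:
    """k-sample log-rank test on a sequence of record collections."""
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for gi, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {gi} has zero subjects")
    times, events, labels = [], [], []
    for gi, g in enumerate(groups):
        t, e = records_to_arrays(g)
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, gi))
    res = multivariate_logrank_test(np.concatenate(times), np.concatenate(labels),
                                    np.concatenate(events))
    return LogRankResult(statistic=float(res.test_statistic),
                         p_value=float(res.p_value), df=len(groups) - 1)


# ------------------------------------------------------- normalisation / groups
def normalize_risks(log_hazards) -> np.ndarray:
    """Z-score log-hazards over the cohort (mean 0, SD 1)."""
    h = np.asarray(log_hazards, dtype=np.float64)
    if h.size == 0:
        raise ValueError("empty input")
    sd = h.std()
    if sd == 0:
        warnings.warn("constant risks: normalized scores set to 0", stacklevel=2)
        return np.zeros_like(h)
    return (h - h.mean()) / sd


def stratify_by_risk(predictions) -> list[str]:
    """Assign low/mid/high tertile labels by normalised risk.

    Accepts either :class:`RiskPrediction` objects (``risk_group`` is filled
    in place) or a plain risk array.  Cut points are the 33rd/66th
    percentiles realised as rank tertiles: subjects are stably sorted by
    risk and split into three nearly equal groups (sizes differ by at most
    one).  Ties at a cut point are resolved by the stable sort order, i.e.
    by original position — deterministic and documented.
    """
    if len(predictions) < 3:
        raise ValueError("need at least 3 patients to form tertiles")
    if isinstance(predictions[0], RiskPrediction):
        raw = np.asarray([p.log_hazard for p in predictions], dtype=np.float64)
    else:
        raw = np.asarray(predictions, dtype=np.float64)
    norm = normalize_risks(raw)
    n = norm.size
    order = np.argsort(norm, kind="stable")
    labels = np.empty(n, dtype=object)
    bounds = [len(chunk) for chunk in np.array_split(np.arange(n), 3)]
    start = 0
    for size, name in zip(bounds, RISK_GROUPS):
        labels[order[start:start + size]] = name
        start += size
    labels = list(labels)
    if isinstance(predictions[0], RiskPrediction):
        for p, z, lab in zip(predictions, norm, labels):
            p.normalized_risk = float(z)
            p.risk_group = lab
    return labels
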