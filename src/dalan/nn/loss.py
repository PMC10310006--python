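"""Differentiable Cox partial-likelihood loss for minibatch training.

The negative partial log-likelihood over a batch is

    L = - sum_{i: event} [ h_i - log sum_{j: t_j >= t_i} exp(h_j) ],

with the risk set formed *within the batch* and tied times included in each
other's risk sets (Breslow-style).  The log-sum-exp runs over a descending
time sort with a global max shift, so the loss stays finite for any hazard
scale.  By default the sum is divided by the number of events so batch size
does not rescale gradients.
"""

from __future__ import annotations

import warnings

import numpy as np

from .tensor import Tensor

__all__ = ["cox_ph_loss"]


def cox_ph_loss(log_hazards: Tensor, times: np.ndarray, events: np.ndarray,
                reduction: str = "mean") -> Tensor:
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    n = times.shape[0]
    if n == 0 or log_hazards.shape[0] != n:
        raise ValueError("log_hazards, times and events must share a positive length")
    n_events = int(events.sum())
    if n_events == 0:
        warnings.warn("Cox loss batch contains no events; contributing zero loss",
                      stacklevel=2)
        return log_hazards.sum() * 0.0

    order = np.argsort(-times, kind="stable")        # descending time
    t_sorted = times[order]
    e_sorted = events[order]
    h_sorted = log_hazards[order]

    # position of the last member of each tie group in the descending sort:
    # the cumulative logsumexp there covers exactly {j : t_j >= t_i}
    asc = t_sorted[::-1]
    group_end = n - 1 - np.searchsorted(asc, t_sorted, side="left")
    lcse = h_sorted.logcumsumexp(axis=0)
    event_idx = np.flatnonzero(e_sorted == 1)
    terms = h_sorted[event_idx] - lcse[group_end[event_idx]]
    loss = -terms.sum()
    if reduction == "mean":
        loss = loss * (1.0 / n_events)
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return loss
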