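"""Nonparametric survival and cumulative incidence estimators.

Kaplan-Meier product-limit survival (with Greenwood standard errors for
plotting) and the Aalen-Johansen cause-specific cumulative incidence.
Both serve as user-facing descriptives and as model-free oracles for the
standardisation engine.

Tie convention: deaths precede censorings at tied times, so subjects
censored at a death time are still in the risk set for that death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StepCurve", "kaplan_meier", "aalen_johansen", "plot_km_failure"]


@dataclass
class StepCurve:
    """A right-continuous piecewise-constant curve with risk-set bookkeeping."""

    times: np.ndarray
    values: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    start_value: float = 1.0
    se: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def __call__(self, t) -> np.ndarray:
        """Evaluate the step function at ``t`` (right-continuous)."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.full(t.shape, self.start_value)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.maximum(idx, 0)], self.start_value)
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "time": self.times,
            "value": self.values,
            "n_risk": self.n_risk,
            "n_event": self.n_event,
        }
        if self.se is not None:
            d["se"] = self.se
        return pd.DataFrame(d)


def _risk_table(time: np.ndarray, status: np.ndarray):
    """Unique event/censor times with at-risk counts (deaths before censorings)."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    s = status[order]
    uniq, first = np.unique(t, return_index=True)
    n_risk = time.size - first
    return uniq, first, n_risk, s


def kaplan_meier(time: np.ndarray, event: np.ndarray) -> StepCurve:
    """Product-limit estimate of all-cause survival.

    ``event`` is 1 for a death at ``time`` and 0 for censoring.  Returns the
    survival curve; the failure curve is ``1 - values``.
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel().astype(float)
    if np.any(time <= 0):
        raise ValueError("times must be > 0")
    if not np.any(event):
        warnings.warn("no events observed; survival is identically 1", RuntimeWarning)
    uniq, first, n_risk, s_sorted = _risk_table(time, event)
    d = np.add.reduceat(s_sorted, first)
    keep = d > 0
    tj, nj, dj = uniq[keep], n_risk[keep], d[keep]
    S = np.cumprod(1.0 - dj / nj)
    # Greenwood
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(dj / (nj * (nj - dj)))
    se = S * np.sqrt(np.where(np.isfinite(gw), gw, np.nan))
    return StepCurve(times=tj, values=S, n_risk=nj, n_event=dj, start_value=1.0, se=se)


def aalen_johansen(time: np.ndarray, cause: np.ndarray) -> dict[int, StepCurve]:
    """Aalen-Johansen cumulative incidence, one curve per nonzero cause.

    ``CIF_k(t) = sum_{t_j <= t} S(t_j-) d_kj / n_j`` with ``S`` the all-cause
    Kaplan-Meier survival.  With a single cause this reduces exactly to
    ``1 - KM``.
    """
    time = np.asarray(time, dtype=float).ravel()
    cause = np.asarray(cause).ravel().astype(int)
    if np.any(time <= 0):
        raise ValueError("times must be > 0")
    any_event = (cause != 0).astype(float)
    uniq, first, n_risk, s_sorted = _risk_table(time, any_event)
    d_all = np.add.reduceat(s_sorted, first)
    keep = d_all > 0
    tj, nj, dj = uniq[keep], n_risk[keep], d_all[keep]
    S = np.cumprod(1.0 - dj / nj)
    S_minus = np.concatenate([[1.0], S[:-1]])

    order = np.argsort(time, kind="stable")
    cause_sorted = cause[order]
    out: dict[int, StepCurve] = {}
    for k in sorted(set(cause.tolist()) - {0}):
        dk_all = np.add.reduceat((cause_sorted == k).astype(float), first)
        dk = dk_all[keep]
        cif = np.cumsum(S_minus * dk / nj)
        out[k] = StepCurve(
            times=tj, values=cif, n_risk=nj, n_event=dk, start_value=0.0
        )
    return out


def plot_km_failure(time, event, group=None, ax=None, labels=None):
    """Kaplan-Meier failure (1 - S) curves, optionally by group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if group is None:
        group = np.zeros(time.size, dtype=int)
    group = np.asarray(group)
    for g in np.unique(group):
        m = group == g
        km = kaplan_meier(time[m], event[m])
        t_plot = np.concatenate([[0.0], np.repeat(km.times, 2), [time.max()]])
        f = 1.0 - km.values
        v_plot = np.concatenate([[0.0, 0.0], np.repeat(f, 2)[:-1], [f[-1]]])
        label = labels.get(g) if labels else str(g)
        ax.plot(t_plot, v_plot, label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("failure probability")
    ax.legend()
    return ax
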