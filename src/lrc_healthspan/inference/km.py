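"""Left-truncated Kaplan–Meier estimation on the age scale.

Subjects enter the risk set at their entry age (delayed entry) and leave
at their exit age by event or censoring; the product-limit estimator then
uses risk sets ``R(t) = {j : entry_j < t <= exit_j}``.  Estimation is
delegated to lifelines' ``KaplanMeierFitter`` with its ``entry`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["KMCurve", "km_estimate", "median_onset_age", "onset_delay"]


@dataclass
class KMCurve:
    """Product-limit curve with at-risk bookkeeping."""

    ages: np.ndarray          # distinct event ages, ascending
    survival: np.ndarray      # S(age) just after each event age
    at_risk: np.ndarray       # risk-set size at each event age
    censor_ages: np.ndarray   # ages of right-censored exits
    n: int

    def survival_at(self, age: float) -> float:
        """Step-function value of S at ``age``."""
        idx = np.searchsorted(self.ages, age, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def at_risk_at(self, ages) -> np.ndarray:
        """Numbers at risk at arbitrary ages (the 'number at risk' row)."""
        out = []
        for a in np.atleast_1d(ages):
            out.append(int(np.sum((self._entry < a) & (self._exit >= a))))
        return np.array(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(records) -> KMCurve:
    """Left-truncated Kaplan–Meier estimate from survival records."""
    records = list(records)
    if not records:
        raise ValueError("no records for Kaplan-Meier estimation")
    entry = np.array([r.entry_age for r in records], dtype=float)
    exit_ = np.array([r.exit_age for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=int)

    kmf = KaplanMeierFitter()
    kmf.fit(durations=exit_, event_observed=event, entry=entry)
    ev_ages = np.unique(exit_[event == 1])
    surv = np.array([float(kmf.predict(a)) for a in ev_ages])
    at_risk = np.array([int(np.sum((entry < a) & (exit_ >= a))) for a in ev_ages])
    curve = KMCurve(
        ages=ev_ages,
        survival=surv,
        at_risk=at_risk,
        censor_ages=np.sort(exit_[event == 0]),
        n=len(records),
    )
    curve._entry = entry
    curve._exit = exit_
    return curve


def median_onset_age(curve: KMCurve) -> float | None:
    """Smallest age at which S drops to <= 0.5, or None if never reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.ages[below[0]])


def onset_delay(curve_ref: KMCurve, curve_cmp: KMCurve) -> float | None:
    """Difference in median onset age (comparison minus reference), in years.

    None when either curve never crosses 50% incidence.
    """
    m_ref = median_onset_age(curve_ref)
    m_cmp = median_onset_age(curve_cmp)
    if m_ref is None or m_cmp is None:
        return None
    return m_cmp - m_ref
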