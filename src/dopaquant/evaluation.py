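"""Cohort-level validation statistics.

The study cohort (18 pediatric patients with diffuse gliomas, 9 low-grade /
9 high-grade) ships as a fixture together with the manual uptake ratios T_N
and T_S. The statistics mirror the published validation: Pearson
correlation between score pairs, residual dispersion of one score regressed
on the other (internal-consistency check), an unpaired t-test of scores
against tumor grade, and an overall-survival analysis (Kaplan-Meier +
log-rank) after splitting the cohort at a sensitivity-maximizing cut-off —
the smallest score among deceased patients, which by construction puts
every death in the high-score group (zero false negatives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sstats

EVENT_MARKER = "DOD"  # died of disease


@dataclass
class PatientRecord:
    case_id: int
    age: float              # years
    gender: str             # "F" | "M"
    diagnosis: str          # "PLGG" | "PHGG"
    t_n_manual: float       # T_N, manual lesion-to-normal SUVmax ratio
    t_s_manual: float       # T_S, manual lesion-to-striatum SUVmax ratio
    who_grade: int
    outcome: str            # PR / SD / PD / "PD and DOD"
    follow_up_months: float

    def __post_init__(self) -> None:
        if self.t_n_manual <= 0 or self.t_s_manual <= 0:
            raise ValueError("manual scores must be positive")
        if self.follow_up_months <= 0:
            raise ValueError("follow-up must be positive")
        if (self.diagnosis == "PLGG") != (self.who_grade == 2):
            raise ValueError("PLGG <=> WHO grade 2")

    @property
    def event(self) -> bool:
        """Death of disease during follow-up (the survival endpoint);
        everything else is censored at the end of follow-up."""
        return EVENT_MARKER in self.outcome


# Case, age, gender, diagnosis, T_N, T_S, WHO grade, outcome, FU (months)
_TABLE1 = [
    (1, 12, "F", "PLGG", 1.00, 0.51, 2, "PR", 63),
    (2, 10, "M", "PLGG", 0.91, 0.51, 2, "SD", 46),
    (3, 14, "M", "PLGG", 1.00, 0.40, 2, "SD", 26),
    (4, 11, "F", "PLGG", 1.51, 0.83, 2, "PR", 25),
    (5, 5, "M", "PLGG", 0.98, 0.55, 2, "SD", 12),
    (6, 9, "M", "PLGG", 1.00, 0.60, 2, "SD", 62),
    (7, 8, "M", "PLGG", 2.31, 1.22, 2, "PD", 42),
    (8, 13, "M", "PLGG", 1.34, 0.84, 2, "SD", 48),
    (9, 15, "M", "PLGG", 1.10, 0.76, 2, "PD", 55),
    (10, 6, "F", "PHGG", 1.73, 1.22, 3, "PD and DOD", 10),
    (11, 8, "F", "PHGG", 2.10, 1.40, 3, "PD and DOD", 8),
    (12, 14, "M", "PHGG", 2.04, 1.14, 3, "PD and DOD", 19),
    (13, 16, "F", "PHGG", 3.41, 1.40, 3, "PD and DOD", 9),
    (14, 6, "F", "PHGG", 2.23, 1.58, 4, "PD and DOD", 8),
    (15, 8, "M", "PHGG", 2.30, 1.40, 4, "PD and DOD", 9),
    (16, 5, "M", "PHGG", 2.26, 1.21, 4, "PD and DOD", 10),
    (17, 8, "M", "PHGG", 2.13, 1.39, 4, "PD and DOD", 4),
    (18, 17, "F", "PHGG", 2.34, 1.22, 4, "PD and DOD", 33),
]


def table1_cohort() -> List[PatientRecord]:
    """The 18-patient study cohort with manual scores and outcomes."""
    return [PatientRecord(*row) for row in _TABLE1]


def cohort_frame(records: Sequence[PatientRecord] | None = None) -> pd.DataFrame:
    records = list(records) if records is not None else table1_cohort()
    return pd.DataFrame({
        "case_id": [r.case_id for r in records],
        "age": [r.age for r in records],
        "gender": [r.gender for r in records],
        "diagnosis": [r.diagnosis for r in records],
        "T_N": [r.t_n_manual for r in records],
        "T_S": [r.t_s_manual for r in records],
        "who_grade": [r.who_grade for r in records],
        "outcome": [r.outcome for r in records],
        "follow_up_months": [r.follow_up_months for r in records],
        "event": [r.event for r in records],
    })


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation and its two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r = sstats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def residual_dispersion(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample SD (n-1) of the residuals of the OLS fit of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() == 0:
        raise ValueError("degenerate predictor")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(np.std(resid, ddof=1))


def two_sample_ttest(a: Sequence[float], b: Sequence[float],
                     welch: bool = False) -> Tuple[float, float]:
    """Unpaired two-sided t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    res = sstats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def probability_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_estimate(times: Sequence[float],
                events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier estimate; censored subjects are event-free at their
    last follow-up."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tl = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    return SurvivalCurve(times=tl, survival=surv, at_risk=at_risk)


def logrank(times_a: Sequence[float], events_a: Sequence[bool],
            times_b: Sequence[float], events_b: Sequence[bool],
            ) -> Tuple[float, float]:
    """Two-sample log-rank test (1 df chi-square, two-sided p).

    With no events in either group the test is undefined; (0.0, 1.0) is
    returned by convention.
    """
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        return 0.0, 1.0
    res = logrank_test(times_a, times_b, event_observed_A=ea,
                       event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def sensitivity_cutoff(scores: Sequence[float],
                       events: Sequence[bool]) -> float:
    """Smallest score among subjects with an event.

    Splitting at this value (high group: score >= cutoff) guarantees zero
    false negatives: every deceased subject lands in the high group.
    """
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events, dtype=bool)
    if scores.shape != events.shape:
        raise ValueError("scores/events length mismatch")
    if not events.any():
        raise ValueError("cutoff undefined: no events")
    return float(scores[events].min())


def survival_split(scores: Sequence[float], times: Sequence[float],
                   events: Sequence[bool]) -> Dict:
    """Cut-off + KM curves + log-rank for one score column."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    cutoff = sensitivity_cutoff(scores, events)
    high = scores >= cutoff
    degenerate = not (~high).any()   # cutoff is the overall minimum
    if degenerate:
        chi2, p = 0.0, 1.0
    else:
        chi2, p = logrank(times[high], events[high],
                          times[~high], events[~high])
    return {
        "cutoff": cutoff,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "events_low": int(events[~high].sum()),
        "degenerate_split": degenerate,
        "logrank_chi2": chi2,
        "logrank_p": p,
        "km_high": km_estimate(times[high], events[high]),
        "km_low": (km_estimate(times[~high], events[~high])
                   if not degenerate else None),
    }


def evaluate_cohort(records: Sequence[PatientRecord] | None = None) -> Dict:
    """The full validation battery on a cohort (default: the study cohort)."""
    df = cohort_frame(records)
    low = df[df.diagnosis == "PLGG"]
    high = df[df.diagnosis == "PHGG"]
    rho_ns, p_ns = pearson(df.T_N, df.T_S)
    out = {
        "n": int(len(df)),
        "n_plgg": int(len(low)),
        "n_phgg": int(len(high)),
        "mean_age": float(df.age.mean()),
        "sd_age": float(df.age.std(ddof=1)),
        "n_events": int(df.event.sum()),
        "pearson_TN_TS": {"rho": rho_ns, "p": p_ns},
        "residual_sigma_TS_on_TN": residual_dispersion(df.T_N, df.T_S),
        "ttest_grade": {},
        "survival": {},
    }
    for col in ("T_N", "T_S"):
        t, p = two_sample_ttest(high[col], low[col])
        out["ttest_grade"][col] = {"t": t, "p": p}
        out["survival"][col] = survival_split(
            df[col], df.follow_up_months, df.event)
    return out
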