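"""Kaplan-Meier estimation, Mantel-Cox log-rank testing, and median-split
survival stratification.

The log-rank machinery follows the classic pooled-risk-set construction:
at each distinct event time the observed events in group A are compared
with their hypergeometric expectation given the pooled risk set, and the
statistic is chi2 = (O_A - E_A)^2 / V on one degree of freedom. The hazard
ratio reported alongside is the observed/expected ratio
HR = (O_A / E_A) / (O_B / E_B) — the "log-rank hazard ratio" convention of
common survival-plotting software — with a 95% CI from
exp(log HR +/- 1.96 sqrt(1/E_A + 1/E_B)). A fitted Cox proportional-
hazards HR (lifelines) can be requested as a secondary estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from lifelines import CoxPHFitter, KaplanMeierFitter


@dataclass
class SurvivalResult:
    chi2: float
    p: float
    hr: float                 # O/E-ratio hazard ratio, group A vs group B
    hr_ci95: tuple[float, float]
    o_a: float
    e_a: float
    o_b: float
    e_b: float
    var: float
    hr_cox: float | None = None


def _check_times(time) -> np.ndarray:
    t = np.asarray(time, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one subject")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and >= 0")
    return t


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan-Meier survival curve as a step table.

    Returns a frame with one row per distinct observed time: ``n_at_risk``,
    ``events``, ``censored`` and the product-limit ``survival`` just after
    that time.
    """
    t = _check_times(time)
    e = np.asarray(event, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    out = pd.DataFrame(
        {
            "n_at_risk": kmf.event_table["at_risk"],
            "events": kmf.event_table["observed"],
            "censored": kmf.event_table["censored"],
            "survival": kmf.survival_function_["KM_estimate"],
        }
    )
    out.index.name = "time"
    return out


def logrank(
    time_a, event_a, time_b, event_b, include_cox: bool = False
) -> SurvivalResult:
    """Two-group Mantel-Cox log-rank test with O/E hazard ratio."""
    ta, tb = _check_times(time_a), _check_times(time_b)
    ea = np.asarray(event_a, dtype=int)
    eb = np.asarray(event_b, dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")

    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones_like(ta, bool), np.zeros_like(tb, bool)])

    o_a = e_a = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = int(events[(times == t)].sum())
        d_a = int(events[(times == t) & in_a].sum())
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)

    o_b = float(ea.sum() + eb.sum()) - o_a
    e_b = float(ea.sum() + eb.sum()) - e_a
    chi2 = (o_a - e_a) ** 2 / var if var > 0 else 0.0
    p = float(st.chi2.sf(chi2, df=1)) if var > 0 else 1.0

    with np.errstate(divide="ignore", invalid="ignore"):
        hr = (o_a / e_a) / (o_b / e_b) if e_a > 0 and e_b > 0 and o_b > 0 else float("inf")
    se = np.sqrt(1 / e_a + 1 / e_b) if e_a > 0 and e_b > 0 else float("nan")
    if np.isfinite(hr) and hr > 0:
        ci = (float(hr * np.exp(-1.96 * se)), float(hr * np.exp(1.96 * se)))
    else:
        ci = (float("nan"), float("nan"))

    hr_cox = None
    if include_cox:
        frame = pd.DataFrame(
            {"time": times, "event": events, "group_a": in_a.astype(int)}
        )
        cph = CoxPHFitter()
        cph.fit(frame, duration_col="time", event_col="event")
        hr_cox = float(np.exp(cph.params_["group_a"]))

    return SurvivalResult(
        chi2=float(chi2), p=p, hr=float(hr), hr_ci95=ci,
        o_a=float(o_a), e_a=float(e_a), o_b=float(o_b), e_b=float(e_b),
        var=float(var), hr_cox=hr_cox,
    )


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples 'hi' (score > median) or 'lo' (score <= median)."""
    s = scores.dropna()
    if s.size < 2:
        raise ValueError("need at least two finite scores")
    if s.nunique() == 1:
        raise ValueError("all scores equal; median split undefined")
    med = s.median()
    return pd.Series(np.where(s > med, "hi", "lo"), index=s.index, name="split")


def truncate_followup(meta: pd.DataFrame, horizon_months: float = 180.0) -> pd.DataFrame:
    """Administratively censor follow-up beyond the horizon (idempotent)."""
    if horizon_months <= 0:
        raise ValueError("horizon must be > 0")
    out = meta.copy()
    over = out["time_months"] > horizon_months
    out.loc[over, "event"] = 0
    out.loc[over, "time_months"] = horizon_months
    return out


def stratified_survival(
    scores: pd.Series,
    meta: pd.DataFrame,
    horizon_months: float | None = 180.0,
    include_cox: bool = False,
):
    """Median-split a score, optionally truncate follow-up, and compare survival.

    Returns ``(result, split, km_hi, km_lo)`` with the 'hi' group as group A,
    so HR > 1 means higher hazard in score-high samples.
    """
    split = median_split(scores)
    sub = meta.loc[split.index]
    if horizon_months is not None:
        sub = truncate_followup(sub, horizon_months)
    hi = sub[split == "hi"]
    lo = sub[split == "lo"]
    result = logrank(
        hi["time_months"], hi["event"], lo["time_months"], lo["event"],
        include_cox=include_cox,
    )
    km_hi = km_estimate(hi["time_months"], hi["event"])
    km_lo = km_estimate(lo["time_months"], lo["event"])
    return result, split, km_hi, km_lo
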