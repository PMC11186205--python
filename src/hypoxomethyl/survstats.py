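"""Survival stratification and association statistics.

Kaplan-Meier curves and the two-group log-rank test are delegated to
lifelines; the univariate Cox proportional-hazards model is fit here by
Newton-Raphson on the partial likelihood with Breslow tie handling (Efron
available behind a flag), with explicit flags for degenerate fits instead of
silent output.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .simdata import SurvivalOutcome


def outcomes_to_frame(outcomes: Sequence[SurvivalOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in outcomes],
            "time_months": [o.time for o in outcomes],
            "event": [int(o.event) for o in outcomes],
            "endpoint": [o.endpoint for o in outcomes],
        }
    )


def frame_to_outcomes(df: pd.DataFrame) -> list[SurvivalOutcome]:
    return [
        SurvivalOutcome(str(r.sample_id), float(r.time_months), bool(r.event), str(r.endpoint))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Dichotomization


def dichotomize(scores: pd.DataFrame, rule: str = "median") -> dict[str, str]:
    """Median split of signature scores: high iff score > median, ties low.

    ``scores`` is the (sample_id, score, ...) frame from score_cohort; samples
    with undefined (NaN) scores are excluded.
    """
    if rule != "median":
        raise ValueError(f"unknown rule {rule!r}")
    sub = scores.dropna(subset=["score"])
    if len(sub) < 2:
        raise ValueError("need >=2 samples with defined scores")
    vals = sub["score"].to_numpy(float)
    if np.ptp(vals) == 0:
        raise ValueError("degenerate split: all scores equal")
    med = float(np.median(vals))
    return {
        str(s): ("high" if v > med else "low")
        for s, v in zip(sub["sample_id"], vals)
    }


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KmCurve:
    times: tuple[float, ...]      # distinct event times, ascending
    survival: tuple[float, ...]   # product-limit estimate after each time
    at_risk: tuple[int, ...]      # risk-set size just before each time
    group_label: str = ""


def km_curve(outcomes: Sequence[SurvivalOutcome], group_label: str = "") -> KmCurve:
    """Product-limit estimator; censored times shrink the risk set only."""
    if len(outcomes) == 0:
        raise ValueError("no outcomes")
    df = outcomes_to_frame(outcomes)
    if (df["time_months"] <= 0).any():
        raise ValueError("non-positive survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time_months"], df["event"])
    tab = kmf.event_table
    ev = tab.loc[tab["observed"] > 0]
    times = tuple(float(t) for t in ev.index)
    surv = tuple(float(kmf.survival_function_at_times(t).iloc[0]) for t in times)
    at_risk = tuple(int(n) for n in ev["at_risk"])
    return KmCurve(times, surv, at_risk, group_label)


def km_curve_frame(curve: KmCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_months": curve.times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
            "group": curve.group_label,
        }
    )


# ---------------------------------------------------------------------------
# Log-rank


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p: float
    n_high: int
    n_low: int
    df: int = 1


def log_rank(
    group_a: Sequence[SurvivalOutcome], group_b: Sequence[SurvivalOutcome]
) -> LogRankResult:
    """Standard two-group log-rank test (chi-square, 1 df)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    fa = outcomes_to_frame(group_a)
    fb = outcomes_to_frame(group_b)
    if fa["event"].sum() + fb["event"].sum() == 0:
        raise ValueError("no events in either group")
    res = logrank_test(
        fa["time_months"], fb["time_months"],
        event_observed_A=fa["event"], event_observed_B=fb["event"],
    )
    return LogRankResult(
        chi_square=float(res.test_statistic),
        p=float(res.p_value),
        n_high=len(group_a),
        n_low=len(group_b),
    )


# ---------------------------------------------------------------------------
# Univariate Cox proportional hazards


@dataclass(frozen=True)
class CoxResult:
    coef: float
    hr: float
    se: float
    wald_p: float
    converged: bool
    flag: str = ""  # "", "degenerate", "separation", "no_convergence"
    score_chi2: float = float("nan")  # score test at beta=0 (log-rank kin)


def _cox_derivatives(beta, x, time, event, ties):
    """Partial log-likelihood, score and information for 1-D covariate.

    Data sorted by time ascending; risk set at t = {time >= t}.
    """
    order = np.argsort(time, kind="mergesort")
    x = x[order]
    time = time[order]
    event = event[order]
    w = np.exp(beta * x)
    # reverse cumulative sums over risk sets
    r0 = np.cumsum(w[::-1])[::-1]
    r1 = np.cumsum((w * x)[::-1])[::-1]
    r2 = np.cumsum((w * x * x)[::-1])[::-1]
    ll = 0.0
    U = 0.0
    info = 0.0
    i = 0
    n = len(x)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        ev = event[i:j].astype(bool)
        d = int(ev.sum())
        if d > 0:
            s = float(x[i:j][ev].sum())
            R0, R1, R2 = r0[i], r1[i], r2[i]
            if ties == "breslow":
                ll += beta * s - d * np.log(R0)
                U += s - d * R1 / R0
                info += d * (R2 / R0 - (R1 / R0) ** 2)
            else:  # efron
                wD = w[i:j][ev]
                xD = x[i:j][ev]
                d0 = float(wD.sum())
                d1 = float((wD * xD).sum())
                d2 = float((wD * xD * xD).sum())
                for k in range(d):
                    f = k / d
                    e0 = R0 - f * d0
                    e1 = R1 - f * d1
                    e2 = R2 - f * d2
                    ll -= np.log(e0)
                    U -= e1 / e0
                    info += e2 / e0 - (e1 / e0) ** 2
                ll += beta * s
                U += s
        i = j
    return ll, U, info


def cox_univariate(
    covariate,
    outcomes: Sequence[SurvivalOutcome],
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Newton-Raphson fit of a univariate Cox model.

    Degenerate cases are flagged rather than silently reported: a constant
    covariate gives coef 0 with flag 'degenerate'; a monotone likelihood
    (complete separation, |coef| diverging) is flagged 'separation'.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be breslow or efron")
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(outcomes):
        raise ValueError("covariate not aligned with outcomes")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate must be finite")
    df = outcomes_to_frame(outcomes)
    time = df["time_months"].to_numpy(float)
    event = df["event"].to_numpy(int)
    if event.sum() == 0:
        raise ValueError("no events")
    if np.ptp(x) == 0:
        return CoxResult(0.0, 1.0, np.nan, np.nan, True, "degenerate")
    xc = x - x.mean()  # centering: numerical stability only, beta unchanged
    _, U0, I0 = _cox_derivatives(0.0, xc, time, event, ties)
    score_chi2 = U0 * U0 / I0 if I0 > 0 else np.nan
    beta = 0.0
    flag = ""
    converged = False
    for _ in range(max_iter):
        ll, U, info = _cox_derivatives(beta, xc, time, event, ties)
        if info <= 0 or not np.isfinite(info):
            flag = "separation" if abs(beta) > 10 else "degenerate"
            break
        step = U / info
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(beta) > 50:
            flag = "separation"
            break
        if abs(step) < tol:
            converged = True
            break
    if not converged and not flag:
        flag = "no_convergence"
    _, _, info = _cox_derivatives(beta, xc, time, event, ties)
    se = 1.0 / np.sqrt(info) if info > 0 else np.nan
    wald_p = 2.0 * stats.norm.sf(abs(beta) / se) if np.isfinite(se) and se > 0 else np.nan
    return CoxResult(
        float(beta), float(np.exp(beta)), float(se), float(wald_p),
        converged, flag, float(score_chi2),
    )
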