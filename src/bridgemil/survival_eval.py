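"""Survival evaluation statistics.

Harrell's concordance index (implemented here because we pin a specific
tie rule), cross-validation aggregation with a t-interval, median-risk
stratification, Kaplan-Meier curves with the log-rank test (via
lifelines), and univariate Cox proportional-hazards regression by Newton
iteration on the Breslow partial likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ConcordanceResult", "KMResult", "CoxResult",
           "concordance_index", "aggregate_cv", "median_stratify",
           "km_and_logrank", "cox_univariate"]


@dataclass
class ConcordanceResult:
    c_index: float
    n_comparable_pairs: int
    n_concordant: float   # ties counted 0.5


def concordance_index(times, events, risks) -> ConcordanceResult:
    """Harrell's C under right censoring.

    A pair (i, j) is comparable iff t_i < t_j and patient i had the event;
    pairs with exactly equal times are never comparable (including
    event-event ties — rule chosen for symmetry, see docs). A comparable
    pair is concordant when risk_i > risk_j; tied risks count 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    r = np.asarray(risks, dtype=float)
    if not (len(t) == len(e) == len(r)):
        raise ValueError("times, events, risks must have equal length")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    # vectorized pairwise comparison
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    greater = (r[:, None] > r[None, :]) & comparable
    tied = (r[:, None] == r[None, :]) & comparable
    n_conc = float(greater.sum()) + 0.5 * float(tied.sum())
    return ConcordanceResult(n_conc / n_pairs, n_pairs, n_conc)


def aggregate_cv(fold_cs) -> dict:
    """Mean fold statistic with a 95% t-interval (sample sd, k-1 df)."""
    cs = np.asarray(fold_cs, dtype=float)
    k = len(cs)
    mean = float(cs.mean())
    if k < 2:
        return {"mean": mean, "ci_low": None, "ci_high": None,
                "method": "t-interval undefined for a single fold", "k": k}
    sd = float(cs.std(ddof=1))
    half = stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k)
    return {"mean": mean, "ci_low": mean - half, "ci_high": mean + half,
            "method": "t-interval over folds (sample sd, 95%)", "k": k}


def median_stratify(risks) -> np.ndarray:
    """Split at the median risk: > median -> 'high', <= median -> 'low'."""
    r = np.asarray(risks, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least two patients to stratify")
    if np.all(r == r[0]):
        raise ValueError("degenerate stratification: all risks equal")
    med = np.median(r)
    return np.where(r > med, "high", "low")


@dataclass
class KMResult:
    curves: pd.DataFrame          # time, survival, at_risk, group
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float | None
    hr_ci: tuple[float, float] | None
    hr_p: float | None


def km_and_logrank(times, events, groups) -> KMResult:
    """Product-limit curves per group, two-group log-rank test, and the
    hazard ratio of the high-vs-low indicator from univariate Cox."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    if e.sum() == 0:
        raise ValueError("no events in the cohort")
    rows = []
    for lab in labels:
        m = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m], label=str(lab))
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"]
        for time, surv in sf.itertuples():
            rows.append({"time": float(time), "survival": float(surv),
                         "at_risk": int(at_risk.get(time, 0)),
                         "group": str(lab)})
    curves = pd.DataFrame(rows)
    m0 = g == labels[0]
    lr = logrank_test(t[m0], t[~m0], e[m0], e[~m0])
    hr = hr_ci = hr_p = None
    # indicator is 1 for the "high" group when labels are low/high,
    # otherwise for the second label in sorted order
    ref = "high" if set(map(str, labels)) == {"low", "high"} else labels[-1]
    indicator = (g == ref).astype(float)
    if indicator.std() > 0:
        try:
            cox = cox_univariate(t, e, indicator)
            hr, hr_ci, hr_p = cox.hazard_ratio, cox.ci, cox.p
        except ValueError:
            pass
    return KMResult(curves, float(lr.test_statistic), float(lr.p_value),
                    hr, hr_ci, hr_p)


@dataclass
class CoxResult:
    beta: float
    hazard_ratio: float
    ci: tuple[float, float]
    p: float
    diverged: bool


def _cox_score_info(b: float, t, e, x) -> tuple[float, float, float]:
    """Breslow partial log-likelihood, score and information at beta=b."""
    order = np.argsort(-t, kind="stable")   # decreasing time
    ts, es, xs = t[order], e[order], x[order]
    w = np.exp(b * xs)
    cs0 = np.cumsum(w)
    cs1 = np.cumsum(w * xs)
    cs2 = np.cumsum(w * xs * xs)
    ll = score = info = 0.0
    # risk set of an event at time ti = all with t >= ti; with decreasing
    # sort these are the prefix up to the last index sharing time >= ti
    n = len(ts)
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        s0, s1, s2 = cs0[j - 1], cs1[j - 1], cs2[j - 1]
        for idx in range(i, j):
            if es[idx] == 1:
                ll += b * xs[idx] - np.log(s0)
                mu = s1 / s0
                score += xs[idx] - mu
                info += s2 / s0 - mu * mu
        i = j
    return ll, score, info


def cox_univariate(times, events, covariate, max_iter: int = 50,
                   tol: float = 1e-10, beta_cap: float = 15.0) -> CoxResult:
    """Newton-Raphson on the Breslow partial likelihood for one covariate.

    Monotone likelihood (perfect separation) is detected when |beta|
    reaches the cap without the score vanishing; the fit is then flagged
    as diverged with beta held at the cap.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    if e.sum() == 0:
        raise ValueError("no events")
    b = 0.0
    diverged = False
    for _ in range(max_iter):
        _, score, info = _cox_score_info(b, t, e, x)
        if info <= 0:
            diverged = True
            break
        step = score / info
        b_new = float(np.clip(b + step, -beta_cap, beta_cap))
        if abs(b_new - b) < tol:
            b = b_new
            break
        b = b_new
    _, score, info = _cox_score_info(b, t, e, x)
    if abs(b) >= beta_cap - 1e-9 or info <= 0 or abs(score) > 1e-3 * (1 + info):
        diverged = True
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    z = b / se if np.isfinite(se) and se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    if np.isfinite(se):
        with np.errstate(over="ignore"):
            ci = (float(np.exp(b - 1.959963984540054 * se)),
                  float(np.exp(b + 1.959963984540054 * se)))
    else:
        ci = (0.0, np.inf)
    return CoxResult(float(b), float(np.exp(b)), ci, float(p), diverged)
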