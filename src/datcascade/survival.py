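"""Median-split survival screen: Kaplan-Meier curves, log-rank test and a
two-group Cox hazard ratio on overall and progression-free survival.

For each gene, patients are split at the median of its expression (values
exactly at the median go to the low group).  The two groups are compared
with the standard two-group log-rank test on each endpoint, a hazard ratio
is estimated by a single-covariate Cox partial-likelihood fit (Breslow tie
handling), and a gene is selected when either endpoint reaches the
significance level.  No multiplicity correction is applied across genes:
the screen is a permissive candidate filter, not a confirmatory test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "median_split",
    "KaplanMeierCurve",
    "km_estimator",
    "logrank_test",
    "cox_hr",
    "screen_genes",
]

log = logging.getLogger(__name__)


def median_split(expression: Sequence[float]) -> np.ndarray:
    """Boolean high/low labels at the median (ties go to the low group)."""
    x = np.asarray(expression, dtype=float)
    if x.size < 4:
        raise ValueError("median split needs at least 4 patients")
    high = x > np.median(x)
    if high.all() or not high.any():
        raise ValueError("degenerate split: constant or one-sided expression")
    return high


@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit estimate S(t); S(0) = 1."""

    event_times: np.ndarray  # distinct times with >=1 event, ascending
    survival: np.ndarray     # S(t) just after each event time

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if self.event_times.size == 0:  # all censored: S == 1 everywhere
            out = np.ones_like(t)
            return out if out.ndim else float(out)
        ix = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(ix < 0, 1.0, self.survival[np.clip(ix, 0, None)])
        return out if out.ndim else float(out)


def km_estimator(times: Sequence[float], events: Sequence[int]) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i) with d_i
    events and n_i subjects at risk at t_i.  Censored observations leave
    the curve unchanged.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if (t <= 0).any():
        raise ValueError("times must be positive")
    order = np.argsort(t, kind="mergesort")
    t, d = t[order], d[order]
    distinct = np.unique(t[d == 1])
    surv = []
    s = 1.0
    n = t.size
    for ti in distinct:
        n_at_risk = np.sum(t >= ti)
        d_i = np.sum((t == ti) & (d == 1))
        s *= 1.0 - d_i / n_at_risk
        surv.append(s)
    return KaplanMeierCurve(distinct, np.asarray(surv))


def _event_table(groups: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Per distinct event time: (n, n1, d, d1) risk/event counts."""
    distinct = np.unique(times[events == 1])
    for ti in distinct:
        at_risk = times >= ti
        dead = (times == ti) & (events == 1)
        yield at_risk.sum(), (at_risk & groups).sum(), dead.sum(), (dead & groups).sum()


def logrank_test(
    groups: Sequence[bool], times: Sequence[float], events: Sequence[int]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    U = sum over event times of (d1 - expected d1 under the hypergeometric
    null), V the matching variance; stat = U^2 / V on 1 df.  Data with no
    usable variance (e.g. no events) give (0, 1).
    """
    g = np.asarray(groups, dtype=bool)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if g.all() or not g.any():
        raise ValueError("both groups must be non-empty")
    u = 0.0
    v = 0.0
    for n, n1, di, d1 in _event_table(g, t, d):
        e1 = di * n1 / n
        u += d1 - e1
        if n > 1:
            v += di * (n1 / n) * (1 - n1 / n) * (n - di) / (n - 1)
    if v <= 0:
        log.warning("log-rank: zero variance, returning p = 1")
        return 0.0, 1.0
    stat = u * u / v
    return stat, float(stats.chi2.sf(stat, df=1))


def cox_hr(
    groups: Sequence[bool],
    times: Sequence[float],
    events: Sequence[int],
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float], float]:
    """Two-group Cox proportional-hazards fit by Newton-Raphson.

    Breslow approximation for tied event times.  Returns
    (HR, (ci_low, ci_high), Wald p).  A monotone partial likelihood
    (complete separation of event times) yields (nan, (nan, nan), nan).
    """
    g = np.asarray(groups, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if np.sum(d) == 0:
        raise ValueError("no events: hazard ratio not estimable")
    beta = 0.0
    distinct = np.unique(t[d == 1])
    # Precompute per-event-time risk sets
    risk_masks = [t >= ti for ti in distinct]
    d_tot = [int(np.sum((t == ti) & (d == 1))) for ti in distinct]
    d1 = [float(np.sum((t == ti) & (d == 1) & (g == 1))) for ti in distinct]
    for _ in range(50):
        score = 0.0
        info = 0.0
        e = np.exp(beta * g)
        for mask, di, d1i in zip(risk_masks, d_tot, d1):
            s0 = e[mask].sum()
            s1 = (e * g)[mask].sum()
            mean = s1 / s0
            score += d1i - di * mean
            info += di * mean * (1.0 - mean)
        if info <= 1e-12:
            return np.nan, (np.nan, np.nan), np.nan
        step = score / info
        beta += step
        if abs(beta) > 15.0:
            log.warning("Cox fit: monotone likelihood, HR not estimable")
            return np.nan, (np.nan, np.nan), np.nan
        if abs(step) < 1e-10:
            break
    se = 1.0 / np.sqrt(info)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return hr, ci, p


def screen_genes(
    dataset: pd.DataFrame,
    genes: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Median-split log-rank + Cox screen of every gene on OS and PFS.

    ``dataset`` follows the survival table schema: patient_id, one numeric
    column per gene, os_time/os_event, pfs_time/pfs_event.  A gene is
    selected when its log-rank p on either endpoint is below ``alpha``.
    Genes with a degenerate median split are skipped (selected = False,
    statistics NaN) and logged.
    """
    reserved = {"patient_id", "os_time", "os_event", "pfs_time", "pfs_event"}
    if genes is None:
        genes = [c for c in dataset.columns if c not in reserved]
    if int(dataset["os_event"].sum()) + int(dataset["pfs_event"].sum()) == 0:
        raise ValueError("all observations censored: screen cannot test any gene")
    rows = []
    for gene in genes:
        row: dict = {"gene_id": gene}
        try:
            high = median_split(dataset[gene].to_numpy(dtype=float))
        except ValueError as err:
            log.warning("skipping %s: %s", gene, err)
            rows.append(
                {**row, "hr_os": np.nan, "ci_os_low": np.nan, "ci_os_high": np.nan,
                 "p_os": np.nan, "hr_pfs": np.nan, "ci_pfs_low": np.nan,
                 "ci_pfs_high": np.nan, "p_pfs": np.nan, "selected": False}
            )
            continue
        for endpoint in ("os", "pfs"):
            t = dataset[f"{endpoint}_time"].to_numpy(dtype=float)
            e = dataset[f"{endpoint}_event"].to_numpy(dtype=int)
            if e.sum() == 0:
                row[f"hr_{endpoint}"] = np.nan
                row[f"ci_{endpoint}_low"] = np.nan
                row[f"ci_{endpoint}_high"] = np.nan
                row[f"p_{endpoint}"] = np.nan
                continue
            _, p = logrank_test(high, t, e)
            hr, ci, _ = cox_hr(high, t, e)
            row[f"hr_{endpoint}"] = hr
            row[f"ci_{endpoint}_low"] = ci[0]
            row[f"ci_{endpoint}_high"] = ci[1]
            row[f"p_{endpoint}"] = p
        p_os = row.get("p_os", np.nan)
        p_pfs = row.get("p_pfs", np.nan)
        row["selected"] = bool(
            (np.isfinite(p_os) and p_os < alpha)
            or (np.isfinite(p_pfs) and p_pfs < alpha)
        )
        rows.append(row)
    return pd.DataFrame(rows)
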