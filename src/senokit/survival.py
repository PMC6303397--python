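"""Kaplan-Meier estimation and the Gehan-Breslow-Wilcoxon weighted log-rank test.

The product-limit estimator and its median (smallest event time with
S(t) <= 0.5) summarize each cohort; group differences are tested with the
Gehan-Breslow-Wilcoxon test — the weighted log-rank statistic with weight
w_j = number at risk at the j-th pooled event time, which emphasizes early
deaths.  The k-sample version forms the chi-square statistic U' V^{-1} U over
the first k-1 groups with the full hypergeometric covariance (tie-corrected)
on k-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError

REQUIRED_COLUMNS = ("group", "time_days", "event")


def validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataValidationError(f"survival table missing columns: {missing}")
    t = table["time_days"].to_numpy(dtype=float)
    if np.any(t <= 0) or np.any(~np.isfinite(t)):
        raise DataValidationError("time_days must be positive and finite")
    ev = table["event"].to_numpy()
    if not set(np.unique(ev)) <= {0, 1}:
        raise DataValidationError("event must be 0 (censored) or 1 (death)")
    return table


NOT_REACHED = "not reached"


@dataclass
class KMEstimate:
    """Product-limit survival curve for one group.

    ``times`` are the distinct event times; ``survival[i]`` is S just after
    ``times[i]``.  Censorings tied with events at the same time leave the
    risk set after the events are counted.
    """

    group: str
    times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    n_subjects: int

    @property
    def median(self) -> float | str:
        below = self.survival <= 0.5 + 1e-12
        if not below.any():
            return NOT_REACHED
        return float(self.times[np.argmax(below)])

    def survival_at(self, t: float) -> float:
        if self.times.size == 0 or t < self.times[0]:
            return 1.0
        return float(self.survival[np.searchsorted(self.times, t, side="right") - 1])

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(table: pd.DataFrame, group: str) -> KMEstimate:
    """Kaplan-Meier product-limit estimate for one group."""
    validate_survival_table(table)
    sub = table[table["group"] == group]
    if len(sub) == 0:
        raise DataValidationError(f"group '{group}' not present in the survival table")
    t = sub["time_days"].to_numpy(dtype=float)
    e = sub["event"].to_numpy(dtype=int)
    event_times = np.unique(t[e == 1])
    n = len(sub)
    times, at_risk, deaths, surv = [], [], [], []
    s = 1.0
    for tj in event_times:
        nj = int(np.sum(t >= tj))  # ties: events counted before censorings leave
        dj = int(np.sum((t == tj) & (e == 1)))
        s *= 1.0 - dj / nj
        times.append(tj)
        at_risk.append(nj)
        deaths.append(dj)
        surv.append(s)
    return KMEstimate(
        group=group,
        times=np.array(times),
        n_at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(deaths, dtype=int),
        survival=np.array(surv),
        n_subjects=n,
    )


def median_survival(km: KMEstimate) -> float | str:
    """Smallest event time with S(t) <= 0.5, or "not reached"."""
    return km.median


@dataclass
class GBWResult:
    chi_square: float
    df: int
    p_value: float
    groups: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "groups": list(self.groups),
        }


def gbw_statistic(
    times: np.ndarray, events: np.ndarray, labels: np.ndarray, groups, weighting: str = "gehan"
) -> float:
    """Chi-square statistic of the weighted log-rank test.

    ``weighting="gehan"`` uses w_j = number at risk (Gehan-Breslow-Wilcoxon);
    ``weighting="logrank"`` uses w_j = 1 (standard log-rank, used as an
    internal cross-check mode).
    """
    k = len(groups)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        raise DataValidationError("no events: test statistic undefined")
    U = np.zeros(k)
    V = np.zeros((k, k))
    group_idx = {g: i for i, g in enumerate(groups)}
    gi = np.array([group_idx[g] for g in labels])
    for tj in event_times:
        at_risk = times >= tj
        nj = int(at_risk.sum())
        dj = int(((times == tj) & (events == 1)).sum())
        if nj <= 1:
            continue
        w = float(nj) if weighting == "gehan" else 1.0
        n_gj = np.bincount(gi[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(gi[(times == tj) & (events == 1)], minlength=k).astype(float)
        frac = n_gj / nj
        U += w * (d_gj - frac * dj)
        tie = dj * (nj - dj) / (nj - 1)
        V += w * w * tie * (np.diag(frac) - np.outer(frac, frac))
    Vr = V[: k - 1, : k - 1]
    Ur = U[: k - 1]
    try:
        chi2 = float(Ur @ np.linalg.solve(Vr, Ur))
    except np.linalg.LinAlgError as exc:
        raise DataValidationError("singular variance matrix (too few events)") from exc
    return max(chi2, 0.0)


def gehan_breslow_wilcoxon(
    table: pd.DataFrame, groups=None, weighting: str = "gehan"
) -> GBWResult:
    """k-sample Gehan-Breslow-Wilcoxon test on k-1 degrees of freedom."""
    validate_survival_table(table)
    if groups is None:
        groups = sorted(table["group"].unique())
    groups = list(groups)
    if len(groups) < 2:
        raise DataValidationError("need at least 2 groups to test")
    sub = table[table["group"].isin(groups)]
    counts = sub["group"].value_counts()
    empty = [g for g in groups if counts.get(g, 0) == 0]
    if empty:
        raise DataValidationError(f"group(s) with zero subjects: {empty}")
    times = sub["time_days"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=int)
    labels = sub["group"].to_numpy()
    chi2 = gbw_statistic(times, events, labels, groups, weighting)
    df = len(groups) - 1
    p = float(stats.chi2.sf(chi2, df))
    return GBWResult(chi_square=chi2, df=df, p_value=min(max(p, 0.0), 1.0), groups=groups)


def pairwise_gbw(table: pd.DataFrame, groups=None, weighting: str = "gehan") -> pd.DataFrame:
    """All pairwise two-group tests; one row per pair."""
    validate_survival_table(table)
    if groups is None:
        groups = sorted(table["group"].unique())
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            res = gehan_breslow_wilcoxon(table, [a, b], weighting)
            rows.append(
                {"group_a": a, "group_b": b, "chi_square": res.chi_square, "p_value": res.p_value}
            )
    return pd.DataFrame(rows)
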