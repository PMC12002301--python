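"""Receptor and organ pharmacology quantification.

Covers the quantitative chain of a ligand-receptor deorphanization
study: per-experiment luminescence normalization, four-parameter
logistic (4PL) EC50 fitting, contraction amplitudes normalized to a
reference agonist, cumulative dose-response summaries, stomach-area
time courses, and the pooled two-sample t-test.

The 4PL model in log10-concentration form::

    response = bottom + (top - bottom) / (1 + 10**(hill*(logEC50 - log10 c)))

is fitted by least squares over all replicate points jointly, with a
small multi-start grid over Hill slope and EC50 to avoid local minima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


class DegenerateFitError(ValueError):
    """Dose-response data carry no usable information for a 4PL fit."""


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    log_ec50: float   # log10 molar
    hill: float
    rss: float
    n_points: int

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50


def four_pl(conc: np.ndarray, bottom: float, top: float,
            log_ec50: float, hill: float) -> np.ndarray:
    """Evaluate the 4PL curve at molar concentrations."""
    logc = np.log10(conc)
    return bottom + (top - bottom) / (1 + 10 ** (hill * (log_ec50 - logc)))


def normalize_luminescence(table: pd.DataFrame,
                           experiment_col: str = "experiment",
                           response_col: str = "response") -> pd.DataFrame:
    """Express responses as % of the maximum within each experiment."""
    out = table.copy()

    def _norm(group: pd.Series) -> pd.Series:
        mx = group.max()
        if not mx > 0:
            raise ValueError(
                "experiment with no positive response cannot be normalized")
        return 100.0 * group / mx

    out[response_col] = (table.groupby(experiment_col)[response_col]
                         .transform(_norm))
    return out


def fit_4pl(conc: Sequence[float], resp: Sequence[float]) -> DoseResponseFit:
    """Least-squares 4PL fit over all points jointly.

    Requires >= 4 distinct positive concentrations and some response
    variation. Multi-start initialization: bottom/top from the data
    range, logEC50 at the concentration nearest the half-range
    response, Hill in {0.5, 1, 2} plus ±1 log-unit EC50 jitter; the
    lowest-RSS solution is returned.
    """
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("conc and resp must have equal length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(conc)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.ptp(resp) == 0:
        raise DegenerateFitError("no response variation")
    lo, hi = float(resp.min()), float(resp.max())
    half = (lo + hi) / 2
    log_c = np.log10(conc)
    lec0 = float(log_c[np.argmin(np.abs(resp - half))])

    def residuals(theta):
        b, t, le, h = theta
        return four_pl(conc, b, t, le, h) - resp

    starts = [
        (lo, hi, lec0, 1.0),
        (lo, hi, lec0, 0.5),
        (lo, hi, lec0, 2.0),
        (lo, hi, lec0 + 1.0, 1.0),
        (lo, hi, lec0 - 1.0, 1.0),
    ]
    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(residuals, x0, method="lm",
                                         max_nfev=10_000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise DegenerateFitError("4PL optimization failed from all starts")
    rss, (b, t, le, h) = best
    if h < 0:  # canonicalize: negative Hill with swapped asymptotes
        b, t, h = t, b, -h
    if not t > b:
        raise DegenerateFitError("fitted top <= bottom")
    return DoseResponseFit(bottom=float(b), top=float(t), log_ec50=float(le),
                           hill=float(h), rss=rss, n_points=len(conc))


def normalize_contraction(records: pd.DataFrame,
                          amplitude_col: str = "amplitude",
                          reference_col: str = "reference_amplitude",
                          conc_col: str = "concentration_M",
                          protocol_col: str = "protocol",
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contraction amplitudes as % of the reference agonist response.

    Returns (per-record table with a ``percent`` column, per-concentration
    summary with mean and SEM). For the cumulative (no-wash) protocol
    the value reported at each dose is the response as measured at that
    dose; non-monotone series are flagged per preparation rather than
    forced monotone.
    """
    df = records.copy()
    if (df[reference_col] <= 0).any():
        bad = df.loc[df[reference_col] <= 0, "prep_id"].unique()
        raise ValueError(f"missing/invalid reference amplitude for preps "
                         f"{list(bad)}")
    df["percent"] = 100.0 * df[amplitude_col] / df[reference_col]
    df["non_monotone"] = False
    if protocol_col in df.columns:
        for prep, sub in df[df[protocol_col] == "cumulative"].groupby("prep_id"):
            ordered = sub.sort_values(conc_col)["percent"].to_numpy()
            if np.any(np.diff(ordered) < 0):
                df.loc[sub.index, "non_monotone"] = True
    summary = (df.groupby(conc_col)["percent"]
               .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)),
                    n="count")
               .reset_index())
    return df, summary


def area_timecourse(areas: pd.DataFrame, t_inject: float,
                    animal_col: str = "animal", time_col: str = "time_min",
                    area_col: str = "area", group_col: str = "group",
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Everted-area time course as % of each animal's pre-injection area.

    The pre-injection baseline is the last measurement at or before
    ``t_inject``. Returns (per-animal normalized table, per-group
    per-time mean ± SEM summary).
    """
    df = areas.copy()
    pct = np.empty(len(df))
    for animal, sub in df.groupby(animal_col):
        pre = sub[sub[time_col] <= t_inject].sort_values(time_col)
        if pre.empty:
            raise ValueError(f"animal {animal!r} has no pre-injection point")
        base = float(pre[area_col].iloc[-1])
        if base <= 0:
            raise ValueError(f"animal {animal!r} has non-positive baseline")
        pct[df.index.get_indexer(sub.index)] = \
            100.0 * sub[area_col].to_numpy() / base
    df["percent"] = pct
    keys = [c for c in (group_col, time_col) if c in df.columns]
    summary = (df.groupby(keys)["percent"]
               .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)),
                    n="count")
               .reset_index())
    return df, summary


def compare_groups(x: Sequence[float], y: Sequence[float],
                   welch: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t-test (pooled Student's form by default).

    Returns (t statistic, p). Degenerate zero-variance input yields
    p = 1 for equal means and p = 0 for unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, 1.0
        return float("inf") if x[0] > y[0] else float("-inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)
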