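"""Cohort-level inference: exact/contingency tests, FDR control, and
survival analysis.

Standard tests are delegated to scipy/statsmodels/lifelines; the Yates-
corrected chi-squared and the log-rank statistic are computed directly so
that the clamped continuity correction and the O/E/V decomposition are
available (both are cross-checked against the library implementations in
the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    event: str
    variable: str
    test: str  # {fisher, t}
    statistic: float
    p: float
    q: float = float("nan")
    note: str = ""


@dataclass
class SurvivalSummary:
    group: str
    n: int
    median: Optional[float]  # days; None if S never reaches 0.5
    curve: pd.DataFrame  # columns: time, survival


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass method:
    the sum of hypergeometric probabilities of all tables with fixed margins
    at most as probable as the observed one).  A zero margin gives p = 1."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def welch_t(x, y) -> tuple[float, float]:
    """Welch two-sample t with Satterthwaite degrees of freedom, two-sided."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    stat, p = sps.ttest_ind(x, y, equal_var=False)
    return float(stat), float(p)


def chi2_yates(table) -> tuple[float, float]:
    """Chi-squared test with Yates continuity correction:
    sum over cells of max(|O - E| - 0.5, 0)^2 / E on 1 df.

    The correction is clamped at zero, so near-null tables give exactly 0
    rather than a sign-flipped correction.
    """
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    rows, cols, n = t.sum(axis=1), t.sum(axis=0), t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin")
    expected = np.outer(rows, cols) / n
    stat = float(np.sum(np.maximum(np.abs(t - expected) - 0.5, 0.0) ** 2 / expected))
    return stat, float(sps.chi2.sf(stat, df=1))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), in the
    input order, capped at 1."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate_segments(
    cohort_data: pd.DataFrame,
    event_columns: Sequence[str],
    categorical: Sequence[str] = ("idh_status", "sex"),
    quantitative: Sequence[str] = ("age", "kps"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Association of each binary event with each phenotype variable.

    Categorical variables: Fisher exact on the event x level table (the
    variable is reduced to its two most frequent non-missing levels).
    Quantitative variables: Welch t between carriers and non-carriers.
    BH adjustment is applied per variable across events.  Monomorphic
    events are skipped with a note.
    """
    results: list[AssociationResult] = []
    for var in list(categorical) + list(quantitative):
        if var not in cohort_data.columns:
            continue
        var_results = []
        for ev in event_columns:
            carrier = cohort_data[ev].astype(float)
            if carrier.nunique(dropna=True) < 2:
                results.append(
                    AssociationResult(ev, var, "skipped", float("nan"),
                                      float("nan"), note="monomorphic event")
                )
                continue
            if var in categorical:
                col = cohort_data[var].astype("string")
                keep = col.notna() & (col != "missing")
                levels = col[keep].value_counts().index[:2]
                if len(levels) < 2:
                    continue
                tab = np.zeros((2, 2), dtype=np.int64)
                for i, lev in enumerate(levels):
                    sel = keep & (col == lev)
                    tab[i, 0] = int((carrier[sel] == 1).sum())
                    tab[i, 1] = int((carrier[sel] == 0).sum())
                p = fisher_exact_2x2(tab)
                odds = sps.contingency.odds_ratio(tab).statistic
                var_results.append(
                    AssociationResult(ev, var, "fisher", float(odds), p)
                )
            else:
                vals = cohort_data[var].astype(float)
                x = vals[(carrier == 1) & vals.notna()]
                y = vals[(carrier == 0) & vals.notna()]
                if len(x) < 2 or len(y) < 2:
                    continue
                try:
                    stat, p = welch_t(x, y)
                except ValueError:
                    continue
                var_results.append(AssociationResult(ev, var, "t", stat, p))
        if var_results:
            q = bh_adjust([r.p for r in var_results])
            for r, qi in zip(var_results, q):
                r.q = float(qi)
            results.extend(var_results)
    df = pd.DataFrame([vars(r) for r in results])
    if len(df):
        df["significant"] = df["q"] <= alpha
    return df


def km_curve(times, events) -> tuple[pd.DataFrame, Optional[float]]:
    """Kaplan-Meier product-limit estimator.

    Returns (step function with columns time/survival, median).  The median
    is the earliest time with S(t) <= 0.5, None when never reached.
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["time", "survival"]
    med = kmf.median_survival_time_
    return sf, (None if np.isinf(med) else float(med))


def logrank(times, events, groups) -> tuple[float, float, dict]:
    """Two-group log-rank test: observed minus expected events with
    hypergeometric variance, summed over event times, on 1 df.

    Returns (chi2, p, components) where components holds O/E/V for the
    first group (sorted group labels).  No events at all gives p = 1.
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    g0 = groups == levels[0]
    if g0.all() or (~g0).all():
        raise ValueError("both groups must be nonempty")

    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n0 = int((at_risk & g0).sum())
        d = int((events == 1)[times == t].sum())
        d0 = int(((events == 1) & g0)[times == t].sum())
        O += d0
        E += d * n0 / n
        if n > 1:
            V += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0, {"O": O, "E": E, "V": V, "group": str(levels[0])}
    chi2 = (O - E) ** 2 / V
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p, {"O": O, "E": E, "V": V, "group": str(levels[0])}
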