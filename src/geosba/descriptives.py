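"""Bivariate tables, chi-squared tests, monthly uptake series and correlograms.

Implements the descriptive layer of the analysis: percentage of skilled
births per policy era by background characteristic (with Pearson chi-squared
tests for change across eras), mean/quartile summaries of the continuous
covariates by attendance group, the monthly skilled-birth proportion series,
its correlogram, and the policy-transition lag comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_types import PolicyPeriod, SurveyTable

PERIOD_ORDER = [p.value for p in PolicyPeriod]


def _require_periods(table: SurveyTable) -> pd.DataFrame:
    if "policy_period" not in table.df.columns:
        table = table.with_policy_periods()
    return table.df


@dataclass
class CrossTab:
    """Skilled-birth percentages by category level and policy era.

    ``cells`` holds one row per (level, period) with the percentage skilled
    (one decimal) and denominator n; ``tests`` holds the per-level Pearson
    chi-squared for change across eras (no continuity correction; df
    adjusted, and flagged, when an era is empty for that level).
    """

    variable: str
    cells: pd.DataFrame    # columns: level, period, pct, n, n_skilled
    tests: pd.DataFrame    # columns: level, chi2, df, p, df_adjusted

    def overall_column(self) -> pd.DataFrame:
        """Pooled percentage and n per level across all eras."""
        g = self.cells.groupby("level", sort=False)[["n", "n_skilled"]].sum()
        g["pct"] = (100.0 * g["n_skilled"] / g["n"]).round(1)
        return g.reset_index()


def policy_crosstab(table: SurveyTable, by: str | None = None) -> CrossTab:
    """Cross-tabulate skilled-birth uptake by policy era.

    ``by=None`` gives the single "overall" row. The chi-squared statistic
    tests the 2 x (eras present) table of (skilled, unskilled) counts for
    each row level; with a single era present no test is computed.
    """
    df = _require_periods(table)
    level_col = df[by].astype(str) if by else pd.Series("overall", index=df.index)
    levels = (
        [str(v) for v in dict.fromkeys(level_col)]
        if by
        else ["overall"]
    )

    cell_rows, test_rows = [], []
    for level in levels:
        sub = df.loc[level_col == level]
        counts = []
        for period in PERIOD_ORDER:
            grp = sub.loc[sub["policy_period"] == period, "outcome"]
            n = int(len(grp))
            k = int(grp.sum())
            pct = round(100.0 * k / n, 1) if n else float("nan")
            cell_rows.append(
                {"level": level, "period": period, "pct": pct, "n": n, "n_skilled": k}
            )
            if n > 0:
                counts.append((k, n - k))
        arr = np.array(counts, dtype=float).T  # 2 x eras-present
        df_adjusted = arr.shape[1] < len(PERIOD_ORDER) if counts else True
        if len(counts) >= 2 and arr.sum() > 0 and (arr.sum(axis=1) > 0).all():
            chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
            test_rows.append(
                {"level": level, "chi2": chi2, "df": dof, "p": p,
                 "df_adjusted": df_adjusted}
            )
        else:
            test_rows.append(
                {"level": level, "chi2": np.nan, "df": 0, "p": np.nan,
                 "df_adjusted": df_adjusted}
            )
    return CrossTab(by or "overall", pd.DataFrame(cell_rows), pd.DataFrame(test_rows))


def pooled_percentage(period_percentages, period_ns) -> float:
    """Pool era-wise percentages into an overall percentage.

    Skilled counts are reconstructed as ``round(pct * n / 100)`` per era,
    pooled, and expressed as a one-decimal percentage of the pooled n.
    """
    pct = np.asarray(period_percentages, dtype=float)
    ns = np.asarray(period_ns, dtype=float)
    if pct.shape != ns.shape:
        raise ValueError("percentage and n vectors differ in length")
    if (ns <= 0).any():
        raise ValueError("denominators must be positive")
    counts = np.round(pct * ns / 100.0)
    return round(100.0 * counts.sum() / ns.sum(), 1)


def continuous_summary(table: SurveyTable, covariates=None) -> pd.DataFrame:
    """Mean, 95% normal-approximation CI and quartiles by attendance group.

    Quartiles use linear interpolation between closest ranks.
    """
    df = table.df
    covariates = covariates or ["maternal_age", "parity", "anc_visits", "distance_km"]
    rows = []
    for skilled, label in ((1, "skilled"), (0, "unskilled")):
        grp = df.loc[df["outcome"] == skilled]
        if len(grp) < 2:
            raise RuntimeError(f"group {label!r} has fewer than 2 records")
        for cov in covariates:
            x = grp[cov].to_numpy(dtype=float)
            mean = x.mean()
            se = x.std(ddof=1) / np.sqrt(x.size)
            q1, q2, q3 = np.percentile(x, [25, 50, 75], method="linear")
            rows.append(
                {
                    "group": label,
                    "covariate": cov,
                    "mean": mean,
                    "ci_low": mean - 1.96 * se,
                    "ci_high": mean + 1.96 * se,
                    "q1": q1,
                    "median": q2,
                    "q3": q3,
                    "n": x.size,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MonthlySeries:
    """Per-calendar-month proportion of skilled births over the window."""

    months: np.ndarray       # contiguous CMC month indices
    proportion: np.ndarray   # NaN where a month has no births
    births: np.ndarray

    def __len__(self) -> int:
        return self.months.size


def monthly_series(table: SurveyTable) -> MonthlySeries:
    """Monthly skilled-birth proportions; empty months are missing, not zero."""
    df = table.df
    if len(df) == 0:
        raise ValueError("empty table")
    lo, hi = table.window
    months = np.arange(lo, hi + 1)
    counts = df.groupby("birth_month")["outcome"].agg(["size", "sum"])
    n = np.zeros(months.size)
    k = np.zeros(months.size)
    present = counts.index.to_numpy() - lo
    n[present] = counts["size"].to_numpy()
    k[present] = counts["sum"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    return MonthlySeries(months, prop, n.astype(int))


@dataclass
class Correlogram:
    lags: np.ndarray
    autocorrelation: np.ndarray
    significant: np.ndarray   # |r| exceeds the 1.96/sqrt(n) band
    n_effective: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "r": self.autocorrelation,
                "significant": self.significant,
            }
        )


def correlogram(series: MonthlySeries, max_lag: int) -> Correlogram:
    """Sample autocorrelation of the monthly proportion series, lags 1..L.

    Missing months are handled conservatively (pairwise-complete products);
    significance uses the white-noise band |r| > 1.96 / sqrt(n).
    """
    from statsmodels.tsa.stattools import acf

    x = series.proportion
    finite = np.isfinite(x)
    n_eff = int(finite.sum())
    if n_eff < max_lag + 2:
        raise ValueError(f"need >= {max_lag + 2} non-missing months, got {n_eff}")
    if np.nanmax(x) == np.nanmin(x):
        raise ValueError("constant series: autocorrelation undefined")
    r = acf(x, nlags=max_lag, missing="conservative", fft=False)
    lags = np.arange(1, max_lag + 1)
    rr = r[1:]
    band = 1.96 / np.sqrt(n_eff)
    return Correlogram(lags, rr, np.abs(rr) > band, n_eff)


def transition_lag_analysis(
    series: MonthlySeries,
    policy_start_month: int,
    n_lags: int = 8,
    window: int = 8,
) -> pd.DataFrame:
    """Compare pre-policy uptake with the policy-era series at lags 1..n_lags.

    The fixed pre-window is the ``window`` months before the policy start;
    for lag l the pre-window is correlated (Pearson) with the same-length
    window offset forward by l months, so lag ``window`` aligns the
    comparison exactly at the transition point. Significance is p < 0.05.
    """
    if n_lags == 0:
        return pd.DataFrame(columns=["lag", "r", "p", "significant"])
    lo = series.months[0]
    start = policy_start_month - lo
    if start - window < 0 or start + n_lags + window > len(series):
        raise ValueError("insufficient months on either side of the transition")
    pre = series.proportion[start - window : start]
    rows = []
    for lag in range(1, n_lags + 1):
        seg = series.proportion[start - window + lag : start + lag]
        ok = np.isfinite(pre) & np.isfinite(seg)
        if ok.sum() < 3:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(pre[ok], seg[ok])
        rows.append({"lag": lag, "r": r, "p": p, "significant": bool(p < 0.05)})
    return pd.DataFrame(rows)
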