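"""Baseline-characteristics ("table one") construction and chi-square tests.

Binary characteristics are compared between outcome groups with the Yates
continuity-corrected chi-square on the 2x2 cross-tab; multi-level
characteristics use the uncorrected Pearson statistic.  The continuity
correction is floored at |O - E| so the statistic is never negative; that
convention reproduces published clinical baseline tables to their printed
precision.  Significance is flagged at p < .05, unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .data_model import SiteDataset

__all__ = [
    "ContingencyTable",
    "yates_chi_square",
    "pearson_chi_square",
    "build_table_one",
    "printed_statistic",
]


def printed_statistic(stat: float, decimals: int = 1) -> float:
    """Round a chi-square statistic the way clinical tables print it.

    Published tables round half-up and often round an already-2-decimal
    value again to 1 decimal; this double rounding can differ from direct
    1-decimal rounding (5.2467 -> 5.25 -> 5.3).  Values below 0.1 keep two
    decimals (0.006 -> 0.01).
    """
    from decimal import ROUND_HALF_UP, Decimal

    d = Decimal(repr(float(stat)))
    two = d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    if abs(stat) < 0.1 or decimals >= 2:
        return float(two)
    return float(two.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ContingencyTable:
    observed: np.ndarray  # r x c nonnegative integers
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed)
        if self.observed.ndim != 2:
            raise ValueError("observed must be 2-dimensional")
        if (self.observed < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.observed.sum() <= 0:
            raise ValueError("table total must be positive")


def _check_margins(obs: np.ndarray) -> None:
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")


def yates_chi_square(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Continuity-corrected chi-square for a 2x2 table -> (stat, df=1, p).

    statistic = sum (|O - E| - 0.5)^2 / E with the 0.5 correction floored at
    |O - E| (tables with |O - E| < 0.5 everywhere give statistic 0, p = 1).
    """
    obs = table.observed if isinstance(table, ContingencyTable) else np.asarray(table)
    if obs.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables only")
    _check_margins(obs)
    stat, p, df, _ = scipy.stats.chi2_contingency(obs, correction=True)
    return float(stat), int(df), float(p)


def pearson_chi_square(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square for an r x c table -> (stat, df, p)."""
    obs = table.observed if isinstance(table, ContingencyTable) else np.asarray(table)
    _check_margins(obs)
    stat, p, df, expected = scipy.stats.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise ValueError("zero expected cell")
    return float(stat), int(df), float(p)


def crosstab_2x2(site_data: list[SiteDataset], covariate_id: str) -> np.ndarray:
    """Pooled [controls, cases] x [has, lacks] counts for a binary covariate."""
    a = c = n0 = n1 = 0
    found = False
    for site in site_data:
        fm = site.features
        hits = np.flatnonzero(fm.covariates == covariate_id)
        if hits.size == 0:
            continue
        found = True
        col = np.asarray(fm.values[:, hits[0]].todense()).ravel() != 0
        y = site.labels
        a += int(col[y == 0].sum())
        c += int(col[y == 1].sum())
        n0 += int((y == 0).sum())
        n1 += int((y == 1).sum())
    if not found:
        raise KeyError(f"characteristic {covariate_id!r} not found in any site")
    return np.array([[a, n0 - a], [c, n1 - c]])


def build_table_one(
    site_data: list[SiteDataset],
    characteristics: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pooled baseline table: counts, percentages, chi-square, p, flag.

    Each binary characteristic is cross-tabbed against the outcome over all
    sites pooled and tested with the Yates-corrected chi-square.  Returns a
    frame with one row per characteristic and the conventional columns.
    """
    n0 = sum(int((s.labels == 0).sum()) for s in site_data)
    n1 = sum(int((s.labels == 1).sum()) for s in site_data)
    rows = []
    for cid in characteristics:
        tab = crosstab_2x2(site_data, cid)
        a, c = int(tab[0, 0]), int(tab[1, 0])
        if tab[:, 0].sum() == 0 or tab[:, 1].sum() == 0:
            stat, df, p = 0.0, 1, 1.0  # degenerate: identical groups
        else:
            stat, df, p = yates_chi_square(tab)
        rows.append(
            {
                "characteristic": cid,
                "control_n": a,
                "control_pct": 100.0 * a / n0 if n0 else np.nan,
                "case_n": c,
                "case_pct": 100.0 * c / n1 if n1 else np.nan,
                "chi_square": stat,
                "df": df,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows, columns=[
        "characteristic", "control_n", "control_pct", "case_n", "case_pct",
        "chi_square", "df", "p_value", "significant",
    ])
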