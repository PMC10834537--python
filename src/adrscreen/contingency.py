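"""2x2 contingency-table primitives shared by the three screens.

All drug--event screens in this package reduce to a 2x2 table with a fixed
cell semantics::

                    event of interest   no event of interest
    drug of interest        a                   b
    other drugs             c                   d

The registry and laboratory screens use the relative risk

    RR = (a / (a + b)) / (c / (c + d))

with a Katz log-normal confidence interval, while the spontaneous-report
screen uses the disproportionality statistics

    PRR = (a / (a + b)) / (c / (c + d))
    ROR = (a / b) / (c / d)
    IC  = log2( a * n / ((a + c) * (a + b)) ),   n = a + b + c + d.

The sign-coherence identity ``a*n - (a+b)*(a+c) = a*d - b*c`` means that,
on a table with no zero cells, PRR > 1, ROR > 1, IC > 0 and a*d > b*c are
all equivalent statements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as _stats

__all__ = [
    "ContingencyTable",
    "RelativeRiskResult",
    "DisproStats",
    "relative_risk",
    "dispro_stats",
    "katz_interval",
    "log_prr_se",
    "log_ror_se",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Integer 2x2 table with the drug-of-interest / event-of-interest layout."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"cell {name!r} must be a non-negative integer, got {value!r}")
            object.__setattr__(self, name, int(value))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


class RelativeRiskResult(NamedTuple):
    rr: float
    ci_low: float
    ci_high: float


class DisproStats(NamedTuple):
    prr: float
    ror: float
    ic: float
    corrected: bool


def katz_interval(a: float, b: float, c: float, d: float, alpha: float = 0.05) -> tuple[float, float]:
    """Katz log-method confidence interval for the risk ratio.

    exp( ln RR +/- z_{1-alpha/2} * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)) )
    """
    rr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    z = _stats.norm.ppf(1.0 - alpha / 2.0)
    log_rr = math.log(rr)
    return math.exp(log_rr - z * se), math.exp(log_rr + z * se)


def relative_risk(table: ContingencyTable, alpha: float = 0.05) -> RelativeRiskResult:
    """Risk ratio with Katz CI.

    Conventions for zero cells: RR = 0 when a = 0 and c > 0; RR is reported
    as missing (NaN) when c = 0; the CI is missing whenever a = 0 or c = 0.

    Raises
    ------
    ValueError
        If a + b = 0 or c + d = 0 (no exposed or no comparator cases).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    a, b, c, d = table.cells()
    if a + b == 0 or c + d == 0:
        raise ValueError("relative risk undefined: an exposure margin is zero")
    if c == 0:
        return RelativeRiskResult(math.nan, math.nan, math.nan)
    if a == 0:
        return RelativeRiskResult(0.0, math.nan, math.nan)
    rr = (a / (a + b)) / (c / (c + d))
    lo, hi = katz_interval(a, b, c, d, alpha)
    return RelativeRiskResult(rr, lo, hi)


def _needs_correction(a, b, c, d):
    return (a == 0) | (b == 0) | (c == 0) | (d == 0)


def corrected_cells(a, b, c, d):
    """Haldane–Anscombe correction: add 0.5 to all four cells when any is zero.

    Works element-wise on arrays; returns float cells plus a boolean mask of
    tables that were corrected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    mask = _needs_correction(a, b, c, d)
    shift = np.where(mask, 0.5, 0.0)
    return a + shift, b + shift, c + shift, d + shift, mask


def dispro_stats_arrays(a, b, c, d):
    """Vectorised PRR/ROR/IC on (optionally continuity-corrected) cells.

    Returns (prr, ror, ic, corrected_mask). All-zero tables raise.
    """
    a = np.asarray(a)
    if np.any(np.asarray(a) + np.asarray(b) + np.asarray(c) + np.asarray(d) == 0):
        raise ValueError("all-zero contingency table")
    af, bf, cf, df, mask = corrected_cells(a, b, c, d)
    n = af + bf + cf + df
    prr = (af / (af + bf)) / (cf / (cf + df))
    ror = (af / bf) / (cf / df)
    ic = np.log2(af * n / ((af + cf) * (af + bf)))
    return prr, ror, ic, mask


def dispro_stats(table: ContingencyTable) -> DisproStats:
    """PRR, ROR and BCPNN information component for one table.

    When any cell is zero, 0.5 is added to all four cells before computing
    the point estimates and the result is flagged ``corrected``.
    """
    a, b, c, d = table.cells()
    if a + b == 0 or c + d == 0:
        raise ValueError("disproportionality undefined: an exposure margin is zero")
    prr, ror, ic, mask = dispro_stats_arrays(a, b, c, d)
    return DisproStats(float(prr), float(ror), float(ic), bool(mask))


def log_prr_se(a, b, c, d):
    """Standard error of log PRR: sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    return np.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))


def log_ror_se(a, b, c, d):
    """Standard error of log ROR: sqrt(1/a + 1/b + 1/c + 1/d)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    return np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
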