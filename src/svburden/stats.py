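"""2x2 carrier statistics: odds ratio, chi-square, Fisher exact,
Bonferroni correction and Fisher's combined-probability meta-analysis.

The contingency table convention throughout is

    a = case carriers        b = case non-carriers
    c = control carriers     d = control non-carriers

so the carrier odds ratio is (a*d)/(b*c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "odds_ratio",
    "odds_ratio_ci",
    "chi_square_test",
    "fisher_exact_test",
    "bonferroni_adjust",
    "meta_combine",
    "MetaResult",
]


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def degenerate(self) -> bool:
        """True when a row or column margin is zero."""
        return (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0)


def odds_ratio(t: ContingencyTable, zero_correction: str = "haldane") -> float:
    """Carrier odds ratio (a*d)/(b*c).

    With ``zero_correction="haldane"`` (default) 0.5 is added to every cell
    whenever any cell is zero; with ``"none"`` a zero denominator yields
    +inf (or raises when both margins collapse).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        if zero_correction == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        elif (a == 0 and c == 0) or (b == 0 and d == 0) \
                or (a == 0 and b == 0) or (c == 0 and d == 0):
            raise ZeroDivisionError("odds ratio undefined: zero margin")
        elif b * c == 0:
            return math.inf
    return (a * d) / (b * c)


def odds_ratio_ci(t: ContingencyTable, alpha: float = 0.05) -> tuple[float, float]:
    """Woolf log-OR confidence interval (Haldane-corrected on zero cells)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    lor = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    return math.exp(lor - z * se), math.exp(lor + z * se)


def chi_square_test(t: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on the 2x2 table (1 df).

    Returns (statistic, p).  A zero row/column margin makes the test
    undefined; such tables carry no association signal and report
    (0.0, 1.0).
    """
    if t.total == 0 or t.degenerate:
        return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(t.as_array(), correction=yates)
    return float(stat), float(p)


def fisher_exact_test(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities not
    exceeding the observed table's, margins fixed."""
    return float(sps.fisher_exact(t.as_array(), alternative="two-sided").pvalue)


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni correction: p*m capped at 1.

    ``m`` defaults to the number of p-values; an override supports families
    defined over a different test count.
    """
    ps = list(p_values)
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, p * m) for p in ps]


@dataclass(frozen=True)
class MetaResult:
    p_values: tuple[float, ...]
    statistic: float    # -2 * sum(log p)
    p: float


def meta_combine(p_values: Sequence[float]) -> MetaResult:
    """Fisher's combined probability test over per-stratum p-values.

    X = -2 * sum(ln p_i) follows chi-square with 2k df under the null; the
    combined p is its upper tail.  A single input is returned unchanged
    (the df=2 tail exp(-X/2) is exactly p).  p=0 is rejected — substitute
    the smallest representable p upstream if a stratum underflows.
    """
    ps = tuple(float(p) for p in p_values)
    if not ps:
        raise ValueError("no p-values to combine")
    for p in ps:
        if p <= 0.0 or p > 1.0:
            raise ValueError(
                f"p-value {p} outside (0, 1]; exact zeros must be replaced "
                "with the smallest representable probability")
    stat = -2.0 * sum(math.log(p) for p in ps)
    if len(ps) == 1:
        return MetaResult(ps, stat, ps[0])
    p = float(sps.chi2.sf(stat, 2 * len(ps)))
    return MetaResult(ps, stat, p)
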