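"""Exact 2x2 statistics for cohort comparisons.

Two estimators are used on the amplified-vs-stressed-control tables:
Fisher's exact test (hypergeometric; the two-sided p sums all tables
with point probability <= the observed one), and the Peto one-step odds
ratio, which remains defined when a cell is zero:

    O = a,  E = n1*m1/N,  V = n1*n2*m1*m2 / (N^2 * (N-1)),
    ln OR = (O - E)/V,    95% CI = exp(ln OR +/- z/sqrt(V)).

Report rounding is half-up at the displayed precision; internal values
are kept at full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats as _sps


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a/b = events/non-events in group 1, c/d in group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError("cell counts must be non-negative integers")

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d

    @property
    def m1(self) -> int:
        return self.a + self.c

    @property
    def m2(self) -> int:
        return self.b + self.d

    @property
    def N(self) -> int:
        return self.n1 + self.n2

    def swapped(self) -> "TwoByTwo":
        return TwoByTwo(self.c, self.d, self.a, self.b)


@dataclass
class PetoResult:
    table: TwoByTwo
    O: float
    E: float
    V: float
    ln_or: float
    or_hat: float
    ci95: tuple[float, float]
    z: float = 1.96
    defined: bool = True
    reason: str = ""


def peto_odds_ratio(t: TwoByTwo, z: float = 1.96) -> PetoResult:
    """One-step Peto odds ratio with a normal-approximation CI.

    Hypergeometric expectation and variance under the null; usable with
    zero cells.  When m1 = 0 or m1 = N the table carries no information
    about the odds ratio and the result is flagged undefined.
    """
    O = float(t.a)
    N = t.N
    if t.m1 == 0 or t.m1 == N or t.n1 == 0 or t.n2 == 0:
        return PetoResult(t, O, math.nan, 0.0, math.nan, math.nan, (math.nan, math.nan), z, False,
                          "degenerate margin: no information about the odds ratio")
    E = t.n1 * t.m1 / N
    V = t.n1 * t.n2 * t.m1 * t.m2 / (N**2 * (N - 1))
    ln_or = (O - E) / V
    half = z / math.sqrt(V)
    return PetoResult(
        t, O, E, V, ln_or, math.exp(ln_or), (math.exp(ln_or - half), math.exp(ln_or + half)), z
    )


_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def fisher_exact(t: TwoByTwo, alternative: str = "two_sided") -> float:
    """Exact hypergeometric tail p-value for a 2x2 table.

    ``two_sided`` uses the point-probability (minimum-likelihood) rule:
    the sum of probabilities of all tables with the observed margins
    whose point probability does not exceed the observed table's.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    res = _sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative=_ALTERNATIVES[alternative])
    return float(res.pvalue)


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def proportion_pct(k: int, n: int, decimals: int = 1) -> float:
    """100*k/n rounded half-up to ``decimals`` places."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    return round_half_up(100.0 * k / n, decimals)


@dataclass
class CohortComparison:
    table: TwoByTwo
    peto: PetoResult
    fisher_p: float
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "table": [self.table.a, self.table.b, self.table.c, self.table.d],
            "O": self.peto.O,
            "E": self.peto.E,
            "V": self.peto.V,
            "or": self.peto.or_hat,
            "ci": list(self.peto.ci95),
            "defined": self.peto.defined,
            "fisher_p": self.fisher_p,
        }


def cohort_compare(
    amp_isolates: list[set[str]],
    ctrl_isolates: list[set[str]],
    event_filter,
    label: str = "",
) -> CohortComparison:
    """Compare two cohorts on the fraction of isolates with >= 1 event
    passing ``event_filter`` (a predicate on an isolate's class set).

    The isolate, not the event, is the counting unit.
    """
    if not amp_isolates or not ctrl_isolates:
        raise ValueError("both cohorts must be non-empty")
    a = sum(1 for cls in amp_isolates if event_filter(cls))
    c = sum(1 for cls in ctrl_isolates if event_filter(cls))
    t = TwoByTwo(a, len(amp_isolates) - a, c, len(ctrl_isolates) - c)
    return CohortComparison(t, peto_odds_ratio(t), fisher_exact(t), label)
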