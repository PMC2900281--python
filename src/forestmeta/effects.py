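"""Per-trial effect estimates for binary outcomes.

A trial is summarised by a 2x2 table (events / arm sizes in the treated and
control arms).  Three effect measures are supported:

``log-rr``
    log risk ratio, ln((a/n1)/(c/n0)); pooled on the log scale and reported
    exponentiated.
``log-or``
    log odds ratio, ln(a(n0-c)/(c(n1-a))); same reporting convention.
``rd``
    risk difference a/n1 - c/n0, reported on the natural scale.

Counts may be fractional: expected-count reconstructions of a generative
model produce non-integer cells and every formula here is evaluated on real
numbers.  Integer tables are the special case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats

from .errors import DegenerateTableError, InvalidTableError

#: canonical measure names
LOG_RR = "log-rr"
LOG_OR = "log-or"
RD = "rd"
MEASURES = (LOG_RR, LOG_OR, RD)

#: measures whose point estimates live on a log scale and are displayed
#: exponentiated
RATIO_MEASURES = frozenset({LOG_RR, LOG_OR})

#: user-facing aliases accepted by the CLI and I/O layers
MEASURE_ALIASES = {
    "rr": LOG_RR,
    "or": LOG_OR,
    "rd": RD,
    LOG_RR: LOG_RR,
    LOG_OR: LOG_OR,
}


def canonical_measure(name: str) -> str:
    try:
        return MEASURE_ALIASES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown effect measure {name!r}; expected one of RR, OR, RD")


@dataclass(frozen=True)
class TwoByTwoTable:
    """Events and arm sizes for one two-arm trial.

    ``a``/``n1`` are events/size in the treated arm, ``c``/``n0`` in the
    control arm.  Fractional counts are permitted.
    """

    label: str
    a: float
    n1: float
    c: float
    n0: float
    year: int | None = None

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n0 <= 0:
            raise InvalidTableError(f"{self.label}: arm sizes must be positive")
        if not (0 <= self.a <= self.n1):
            raise InvalidTableError(
                f"{self.label}: treated events {self.a} outside [0, {self.n1}]"
            )
        if not (0 <= self.c <= self.n0):
            raise InvalidTableError(
                f"{self.label}: control events {self.c} outside [0, {self.n0}]"
            )

    @property
    def risk1(self) -> float:
        return self.a / self.n1

    @property
    def risk0(self) -> float:
        return self.c / self.n0

    def swapped(self) -> "TwoByTwoTable":
        """The same trial with treated and control arms exchanged."""
        return replace(self, a=self.c, n1=self.n0, c=self.a, n0=self.n1)


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with its sampling variance for one trial."""

    measure: str
    point: float
    variance: float
    label: str

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.variance < 0:
            raise ValueError(f"{self.label}: negative variance {self.variance}")


def _needs_correction(t: TwoByTwoTable, measure: str) -> bool:
    if measure == RD:
        return False
    if measure == LOG_RR:
        return t.a == 0 or t.c == 0
    # log-OR additionally needs both non-event cells
    return t.a == 0 or t.c == 0 or t.a == t.n1 or t.c == t.n0


def _apply_policy(t: TwoByTwoTable, measure: str, policy: str) -> TwoByTwoTable:
    if not _needs_correction(t, measure):
        return t
    if policy == "error":
        raise DegenerateTableError(
            f"{t.label}: zero cell makes {measure} undefined"
        )
    if policy == "none":
        return t  # caller gets inf/nan downstream; deliberate
    if policy == "halves":
        # standard continuity correction: 0.5 added to all four cells,
        # applied per table and only when needed
        return TwoByTwoTable(
            label=t.label,
            a=t.a + 0.5,
            n1=t.n1 + 1.0,
            c=t.c + 0.5,
            n0=t.n0 + 1.0,
            year=t.year,
        )
    raise ValueError(f"unknown zero-cell policy {policy!r}")


def effect_from_table(
    table: TwoByTwoTable, measure: str = LOG_RR, zero_cell_policy: str = "halves"
) -> EffectEstimate:
    """Effect estimate and sampling variance for one 2x2 table.

    Standard inverse-variance (delta-method) variances:

    * log-RR: 1/a - 1/n1 + 1/c - 1/n0
    * log-OR: 1/a + 1/(n1-a) + 1/c + 1/(n0-c)
    * RD: p1(1-p1)/n1 + p0(1-p0)/n0
    """
    measure = canonical_measure(measure) if measure not in MEASURES else measure
    t = _apply_policy(table, measure, zero_cell_policy)
    if measure == LOG_RR:
        point = math.log(t.risk1 / t.risk0) if t.a > 0 and t.c > 0 else math.nan
        variance = (
            1.0 / t.a - 1.0 / t.n1 + 1.0 / t.c - 1.0 / t.n0
            if t.a > 0 and t.c > 0
            else math.inf
        )
    elif measure == LOG_OR:
        b, d = t.n1 - t.a, t.n0 - t.c
        ok = min(t.a, b, t.c, d) > 0
        point = math.log((t.a * d) / (t.c * b)) if ok else math.nan
        variance = 1.0 / t.a + 1.0 / b + 1.0 / t.c + 1.0 / d if ok else math.inf
    else:  # RD
        p1, p0 = t.risk1, t.risk0
        point = p1 - p0
        variance = p1 * (1 - p1) / t.n1 + p0 * (1 - p0) / t.n0
    return EffectEstimate(measure=measure, point=point, variance=variance, label=t.label)


def confidence_interval(
    estimate: EffectEstimate, level: float = 0.95
) -> tuple[float, float]:
    """Wald confidence interval on the reporting scale.

    Ratio measures are exponentiated; the risk difference stays on the
    natural scale.  A zero variance gives the degenerate point interval.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 * (1 + level))
    half = z * math.sqrt(estimate.variance)
    low, high = estimate.point - half, estimate.point + half
    if estimate.measure in RATIO_MEASURES:
        return math.exp(low), math.exp(high)
    return low, high


def reporting_point(estimate: EffectEstimate) -> float:
    """Point estimate on the reporting scale (exp'd for ratio measures)."""
    if estimate.measure in RATIO_MEASURES:
        return math.exp(estimate.point)
    return estimate.point
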