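"""Heterogeneity statistics and inverse-variance pooling.

Given per-trial effects theta_i with sampling variances v_i this module
computes Cochran's Q, its chi-square p-value, Higgins' I^2, the
DerSimonian-Laird (method-of-moments) between-study variance tau^2, fixed-
and random-effects pooled estimates, and a t-based prediction interval for
the effect in a new trial.

All statistics are functions of the *set* of (theta_i, v_i) pairs: they are
invariant under any permutation of the studies.  This is the blind spot the
package exists to illustrate — a trial-level covariate (such as subgroup
prevalence) can induce a perfectly ordered trend across trials that these
statistics cannot see, because ordering information never enters them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from scipy import special, stats

from .effects import (
    EffectEstimate,
    RATIO_MEASURES,
    TwoByTwoTable,
    effect_from_table,
)
from .errors import HeterogeneityUndefinedError, NoDataError, PredictionIntervalUndefinedError


@dataclass(frozen=True)
class MetaInput:
    """An ordered collection of same-measure effect estimates.

    ``subgroup_props`` and ``years`` are optional trial-level covariates used
    by the forest-plot layouts; the statistics below ignore them.
    """

    estimates: tuple[EffectEstimate, ...]
    subgroup_props: tuple[float | None, ...] | None = None
    years: tuple[int | None, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "estimates", tuple(self.estimates))
        if self.k == 0:
            raise NoDataError("a meta-analysis needs at least one study")
        measures = {e.measure for e in self.estimates}
        if len(measures) > 1:
            raise ValueError(f"mixed effect measures: {sorted(measures)}")
        for e in self.estimates:
            if not e.variance > 0:
                raise ValueError(f"{e.label}: non-positive variance {e.variance}")
        for name in ("subgroup_props", "years"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, tuple(val))
                if len(val) != self.k:
                    raise ValueError(f"{name} length != number of studies")

    @property
    def k(self) -> int:
        return len(self.estimates)

    @property
    def measure(self) -> str:
        return self.estimates[0].measure

    @classmethod
    def from_tables(
        cls,
        tables: list[TwoByTwoTable],
        measure: str = "log-rr",
        subgroup_props: list[float | None] | None = None,
        zero_cell_policy: str = "halves",
    ) -> "MetaInput":
        ests = tuple(effect_from_table(t, measure, zero_cell_policy) for t in tables)
        return cls(
            estimates=ests,
            subgroup_props=tuple(subgroup_props) if subgroup_props is not None else None,
            years=tuple(t.year for t in tables),
        )


@dataclass(frozen=True)
class PooledEstimate:
    point: float
    se: float


@dataclass(frozen=True)
class HeterogeneityResult:
    """Everything a heterogeneity report prints, on the analysis scale."""

    measure: str
    k: int
    Q: float
    df: int
    p_value: float
    I2: float                 # fraction in [0, 1]
    tau2: float
    C: float                  # DL scaling constant sum(w) - sum(w^2)/sum(w)
    fixed: PooledEstimate
    random: PooledEstimate
    prediction_interval: tuple[float, float] | None
    level: float = 0.95


def _canonical(meta: MetaInput) -> list[EffectEstimate]:
    # all statistics here are set functions of the studies; summing in a
    # canonical order makes them bit-identical under input permutations
    return sorted(meta.estimates, key=lambda e: (e.label, e.point, e.variance))


def pool_fixed(meta: MetaInput) -> PooledEstimate:
    """Inverse-variance fixed-effect pooled estimate."""
    ests = _canonical(meta)
    w = [1.0 / e.variance for e in ests]
    sw = sum(w)
    point = sum(wi * e.point for wi, e in zip(w, ests)) / sw
    return PooledEstimate(point=point, se=math.sqrt(1.0 / sw))


def q_statistic(meta: MetaInput) -> tuple[float, int, float]:
    """Cochran's Q, degrees of freedom k-1 and the chi-square p-value.

    Q weights squared deviations from the fixed-effect mean by inverse
    variance; under homogeneity it is chi-square with k-1 df.  The upper
    tail is evaluated through the regularized incomplete gamma function.
    """
    if meta.k < 2:
        raise HeterogeneityUndefinedError("Q needs at least two studies")
    mu = pool_fixed(meta).point
    q = sum((e.point - mu) ** 2 / e.variance for e in _canonical(meta))
    df = meta.k - 1
    p = float(special.gammaincc(df / 2.0, q / 2.0))
    return q, df, p


def i_squared(Q: float, df: int) -> float:
    """I^2 = max(0, (Q - df)/Q), the fraction of variation beyond chance.

    Defined as 0 when Q = 0 (and whenever Q <= df); returned as a fraction,
    formatted as a percentage in user-facing reports.
    """
    if Q < 0 or df < 1:
        raise ValueError("Q must be >= 0 and df >= 1")
    if Q <= df:
        return 0.0
    return (Q - df) / Q


def dl_scaling_constant(meta: MetaInput) -> float:
    w = [1.0 / e.variance for e in _canonical(meta)]
    sw = sum(w)
    return sw - sum(wi * wi for wi in w) / sw


def tau2_dl(meta: MetaInput) -> float:
    """DerSimonian-Laird method-of-moments between-study variance.

    tau^2 = max(0, (Q - df) / C) with C = sum(w) - sum(w^2)/sum(w);
    truncated at zero.
    """
    q, df, _ = q_statistic(meta)
    c = dl_scaling_constant(meta)
    if c <= 0:
        raise HeterogeneityUndefinedError("degenerate weights: C <= 0")
    return max(0.0, (q - df) / c)


def pool_random(meta: MetaInput, tau2: float) -> PooledEstimate:
    """Random-effects pooled estimate with weights 1/(v_i + tau2)."""
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    ests = _canonical(meta)
    w = [1.0 / (e.variance + tau2) for e in ests]
    sw = sum(w)
    point = sum(wi * e.point for wi, e in zip(w, ests)) / sw
    return PooledEstimate(point=point, se=math.sqrt(1.0 / sw))


def prediction_interval(
    random_point: float,
    random_se: float,
    tau2: float,
    k: int,
    level: float = 0.95,
) -> tuple[float, float]:
    """Interval expected to contain the true effect of a new trial.

    Higgins-style: point +- t_{k-2} * sqrt(tau2 + se^2) on the analysis
    scale.  Needs k >= 3 for the t distribution with k-2 df to exist.
    """
    if k < 3:
        raise PredictionIntervalUndefinedError(
            f"prediction interval needs k >= 3 studies, got {k}"
        )
    t = stats.t.ppf(0.5 * (1 + level), df=k - 2)
    half = t * math.sqrt(tau2 + random_se**2)
    return random_point - half, random_point + half


def analyze(meta: MetaInput, level: float = 0.95) -> HeterogeneityResult:
    """Full heterogeneity + pooling report for one meta-analysis."""
    q, df, p = q_statistic(meta)
    i2 = i_squared(q, df)
    c = dl_scaling_constant(meta)
    tau2 = tau2_dl(meta)
    fixed = pool_fixed(meta)
    random = pool_random(meta, tau2)
    pi: tuple[float, float] | None
    if meta.k >= 3:
        pi = prediction_interval(random.point, random.se, tau2, meta.k, level)
    else:
        pi = None
    return HeterogeneityResult(
        measure=meta.measure,
        k=meta.k,
        Q=q,
        df=df,
        p_value=p,
        I2=i2,
        tau2=tau2,
        C=c,
        fixed=fixed,
        random=random,
        prediction_interval=pi,
        level=level,
    )


def compare_measures(
    tables: list[TwoByTwoTable], zero_cell_policy: str = "halves", level: float = 0.95
) -> dict[str, HeterogeneityResult]:
    """Heterogeneity of the same trials under log-RR, log-OR and RD.

    The observed amount of heterogeneity depends on the effect measure: a
    set of trials perfectly homogeneous on the odds-ratio scale is in
    general heterogeneous on the risk-difference scale (and vice versa)
    whenever baseline risks differ.  No cross-measure reconciliation is
    attempted; the three reports are returned side by side.
    """
    if len(tables) < 2:
        raise HeterogeneityUndefinedError("compare_measures needs k >= 2 tables")
    out: dict[str, HeterogeneityResult] = {}
    for measure in ("log-rr", "log-or", "rd"):
        meta = MetaInput.from_tables(tables, measure, zero_cell_policy=zero_cell_policy)
        out[measure] = analyze(meta, level)
    return out


# ---------------------------------------------------------------- reporting

def _fmt(x: float, nd: int = 2) -> str:
    s = f"{x:.{nd}f}"
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return "0" if s in ("-0", "") else s


def _display(point: float, measure: str) -> float:
    return math.exp(point) if measure in RATIO_MEASURES else point


def format_report(res: HeterogeneityResult) -> str:
    """Flat key-value text report in the conventional style, e.g.
    ``Q = 3.29, p = 0.51; I2 = 0%; T2 = 0``."""
    lines = [
        f"measure = {res.measure}, k = {res.k}",
        f"Q = {_fmt(res.Q)}, df = {res.df}, p = {_fmt(res.p_value)}; "
        f"I2 = {_fmt(res.I2 * 100, 1)}%; T2 = {_fmt(res.tau2, 4)}",
        f"fixed effect: {_fmt(_display(res.fixed.point, res.measure), 4)} "
        f"(se of {'log ' if res.measure in RATIO_MEASURES else ''}estimate {_fmt(res.fixed.se, 4)})",
        f"random effects: {_fmt(_display(res.random.point, res.measure), 4)} "
        f"(se of {'log ' if res.measure in RATIO_MEASURES else ''}estimate {_fmt(res.random.se, 4)})",
    ]
    if res.prediction_interval is not None:
        lo, hi = (_display(x, res.measure) for x in res.prediction_interval)
        lines.append(
            f"{int(res.level * 100)}% prediction interval: "
            f"({_fmt(lo, 4)}, {_fmt(hi, 4)})"
        )
    return "\n".join(lines)


def to_json_dict(res: HeterogeneityResult) -> dict:
    """JSON-serializable mirror of the text report (analysis scale)."""
    d = {
        "measure": res.measure,
        "k": res.k,
        "Q": res.Q,
        "df": res.df,
        "p": res.p_value,
        "I2": res.I2,
        "tau2": res.tau2,
        "fixed": {"point": res.fixed.point, "se": res.fixed.se},
        "random": {"point": res.random.point, "se": res.random.se},
        "prediction_interval": list(res.prediction_interval)
        if res.prediction_interval is not None
        else None,
        "level": res.level,
    }
    return d


def to_json(res: HeterogeneityResult) -> str:
    return json.dumps(to_json_dict(res), indent=2)
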