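"""Synthetic meta-analyses with trial-varying subgroup prevalence.

The generative model: ``k`` two-arm trials, 1:1 randomized, with a binary
outcome.  Within trial ``i`` a proportion ``p_i`` of participants belong to
a subgroup (say, women).  Everyone shares the control-arm risk; treatment
multiplies that risk by ``rr_in_subgroup`` inside the subgroup and by
``rr_out_subgroup`` outside it.  Because baseline risk is constant across
strata, the risk ratio is collapsible and the marginal treated risk in
trial ``i`` is ``control_risk * (p_i * rr_in + (1 - p_i) * rr_out)`` — the
trial-level effect drifts smoothly with prevalence while every trial
remains internally consistent with the same subgroup-specific effects.

Two modes:

``expected``
    deterministic expected counts (fractional cells); the noiseless
    skeleton of the design, useful as an exact fixture.
``binomial``
    one seeded binomial draw per arm-by-stratum cell; subgroup sizes stay
    fixed at round(p_i * n) (ties to even) — only outcomes are random.

``hypothetical_fixture`` returns the canonical demonstration scenario:
five trials of 200 subjects, 50% baseline risk, subgroup risk ratio 0.7
versus 1.0 outside, prevalences 0/25/50/75/100%.  Its aggregated effects
look perfectly homogeneous (I2 = 0, tau2 = 0) even though the subgroup
effect is built in — visible in a prevalence-scaled forest plot and
testable in the individual patient data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import TwoByTwoTable
from .errors import InvalidScenarioError
from .ipd import IPDDataset


@dataclass(frozen=True)
class ScenarioConfig:
    k: int
    n_per_arm: tuple[int, ...]
    control_risk: float
    rr_in_subgroup: float
    rr_out_subgroup: float
    subgroup_props: tuple[float, ...]
    mode: str = "expected"
    seed: int | None = None
    years: tuple[int | None, ...] | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_arm", tuple(self.n_per_arm))
        object.__setattr__(self, "subgroup_props", tuple(self.subgroup_props))
        if len(self.n_per_arm) != self.k or len(self.subgroup_props) != self.k:
            raise InvalidScenarioError("n_per_arm and subgroup_props must have length k")
        if not 0 < self.control_risk < 1:
            raise InvalidScenarioError("control_risk must be in (0, 1)")
        if min(self.rr_in_subgroup, self.rr_out_subgroup) <= 0:
            raise InvalidScenarioError("risk ratios must be positive")
        if self.control_risk * max(self.rr_in_subgroup, self.rr_out_subgroup) > 1:
            raise InvalidScenarioError("treated risk exceeds 1 in some stratum")
        if any(not 0 <= p <= 1 for p in self.subgroup_props):
            raise InvalidScenarioError("subgroup proportions must lie in [0, 1]")
        if self.mode not in ("expected", "binomial"):
            raise InvalidScenarioError(f"unknown mode {self.mode!r}")
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(f"trial_{i + 1}" for i in range(self.k))
            )
        if self.years is not None:
            object.__setattr__(self, "years", tuple(self.years))

    def year_of(self, i: int) -> int | None:
        return None if self.years is None else self.years[i]


def hypothetical_fixture() -> ScenarioConfig:
    """The five-trial demonstration scenario.

    200 subjects per trial randomized 1:1, baseline risk 50%, treatment
    risk ratio 0.7 in the subgroup and 1.0 outside, subgroup prevalence
    0/25/50/75/100% across trials.  Years are arbitrary but fixed, chosen
    so that chronological order differs from prevalence order.
    """
    return ScenarioConfig(
        k=5,
        n_per_arm=(100, 100, 100, 100, 100),
        control_risk=0.5,
        rr_in_subgroup=0.7,
        rr_out_subgroup=1.0,
        subgroup_props=(0.0, 0.25, 0.50, 0.75, 1.00),
        mode="expected",
        years=(1986, 1989, 1981, 1992, 1984),
    )


def _stratum_sizes(config: ScenarioConfig, i: int) -> tuple[float, float]:
    """(subgroup size, complement size) per arm for trial i."""
    n = config.n_per_arm[i]
    if config.mode == "binomial":
        n_in = round(config.subgroup_props[i] * n)  # ties to even
        return float(n_in), float(n - n_in)
    n_in = config.subgroup_props[i] * n
    return n_in, n - n_in


def _stratum_risks(config: ScenarioConfig) -> dict[tuple[int, int], float]:
    """Outcome risk by (arm, subgroup) cell."""
    r = config.control_risk
    return {
        (0, 0): r,
        (0, 1): r,
        (1, 0): r * config.rr_out_subgroup,
        (1, 1): r * config.rr_in_subgroup,
    }


def _cells_expected(config: ScenarioConfig) -> list[dict[tuple[int, int], tuple[float, float]]]:
    risks = _stratum_risks(config)
    out = []
    for i in range(config.k):
        n_in, n_out = _stratum_sizes(config, i)
        cells = {}
        for arm in (0, 1):
            for sub, n in ((1, n_in), (0, n_out)):
                cells[(arm, sub)] = (n, n * risks[(arm, sub)])
        out.append(cells)
    return out


def _cells_binomial(
    config: ScenarioConfig, rng: np.random.Generator
) -> list[dict[tuple[int, int], tuple[float, float]]]:
    risks = _stratum_risks(config)
    out = []
    for i in range(config.k):
        n_in, n_out = _stratum_sizes(config, i)
        cells = {}
        for arm in (0, 1):
            for sub, n in ((1, n_in), (0, n_out)):
                n = int(n)
                events = int(rng.binomial(n, risks[(arm, sub)])) if n > 0 else 0
                cells[(arm, sub)] = (float(n), float(events))
        out.append(cells)
    return out


def _cells(
    config: ScenarioConfig, seed: int | None = None
) -> list[dict[tuple[int, int], tuple[float, float]]]:
    if config.mode == "expected":
        return _cells_expected(config)
    use_seed = seed if seed is not None else config.seed
    rng = np.random.default_rng(use_seed)
    return _cells_binomial(config, rng)


def _tables_from_cells(
    config: ScenarioConfig, cells: list[dict[tuple[int, int], tuple[float, float]]]
) -> list[TwoByTwoTable]:
    tables = []
    for i, cell in enumerate(cells):
        n1 = cell[(1, 1)][0] + cell[(1, 0)][0]
        a = cell[(1, 1)][1] + cell[(1, 0)][1]
        n0 = cell[(0, 1)][0] + cell[(0, 0)][0]
        c = cell[(0, 1)][1] + cell[(0, 0)][1]
        tables.append(
            TwoByTwoTable(
                label=config.labels[i], a=a, n1=n1, c=c, n0=n0, year=config.year_of(i)
            )
        )
    return tables


def expected_tables(config: ScenarioConfig) -> list[TwoByTwoTable]:
    """Deterministic expected-count 2x2 tables, one per trial.

    Control events are n0 * control_risk; treated events are
    n1 * control_risk * (p_i * rr_in + (1 - p_i) * rr_out).  Counts are
    fractional in general.
    """
    cfg = config if config.mode == "expected" else _with_mode(config, "expected")
    return _tables_from_cells(cfg, _cells_expected(cfg))


def sample_tables(config: ScenarioConfig, seed: int | None = None) -> list[TwoByTwoTable]:
    """One stochastic realization of the scenario as integer 2x2 tables.

    Subgroup sizes are fixed; events are binomial per arm-by-stratum cell.
    Identical seeds give identical tables.
    """
    cfg = config if config.mode == "binomial" else _with_mode(config, "binomial")
    use_seed = seed if seed is not None else cfg.seed
    rng = np.random.default_rng(use_seed)
    return _tables_from_cells(cfg, _cells_binomial(cfg, rng))


def _with_mode(config: ScenarioConfig, mode: str) -> ScenarioConfig:
    from dataclasses import replace

    return replace(config, mode=mode)


def generate_ipd(config: ScenarioConfig, seed: int | None = None) -> IPDDataset:
    """Participant-level records for the scenario.

    Expected mode emits one weighted record per trial x arm x stratum x
    outcome cell (weight = expected count); binomial mode emits one
    unit-weight record per participant.  Total weight per trial equals the
    trial size in both modes.
    """
    cells = _cells(config, seed)
    rows: list[tuple[str, int, int, int, float]] = []
    for i, cell in enumerate(cells):
        label = config.labels[i]
        for (arm, sub), (n, events) in sorted(cell.items()):
            if n <= 0:
                continue
            if config.mode == "expected":
                if events > 0:
                    rows.append((label, arm, sub, 1, events))
                if n - events > 0:
                    rows.append((label, arm, sub, 0, n - events))
            else:
                rows.extend((label, arm, sub, 1, 1.0) for _ in range(int(events)))
                rows.extend((label, arm, sub, 0, 1.0) for _ in range(int(n - events)))
    df = pd.DataFrame(rows, columns=["trial", "arm", "subgroup", "outcome", "weight"])
    return IPDDataset(df)
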