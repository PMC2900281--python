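"""Individual-patient-data (IPD) analysis.

Aggregated heterogeneity statistics can miss a subgroup effect entirely;
with participant-level records the effect can be tested directly.  Two
routes are implemented:

* stratum-specific Mantel-Haenszel risk ratios pooled across trials, with
  the Greenland-Robins variance for the log risk ratio — used to report the
  treatment effect inside and outside the subgroup on the ratio scale;
* a logistic regression of outcome on treatment, subgroup and their
  interaction, with fixed trial indicator terms to absorb between-trial
  baseline differences.  The interaction coefficient is a log odds ratio;
  a Wald or likelihood-ratio test of it is the formal subgroup test.

Records carry weights so that expected-count (fractional) data and ordinary
one-row-per-participant data flow through identical code paths; fractional
weights enter the likelihood multiplicatively (a quasi-likelihood in the
expected-count case) and standard errors come from the weighted information
matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .effects import TwoByTwoTable
from .errors import InvalidTableError, NonIdentifiableError, NotEstimableError

IPD_COLUMNS = ("trial", "arm", "subgroup", "outcome", "weight")


@dataclass(frozen=True)
class IPDDataset:
    """Weighted participant-level records.

    ``data`` has columns trial (str), arm (0 control / 1 treated),
    subgroup (0/1), outcome (0/1) and weight (> 0, default 1).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in IPD_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"IPD data lacks columns {missing}")
        if "weight" not in df.columns:
            df = df.assign(weight=1.0)
        df = df.copy()
        df["trial"] = df["trial"].astype(str)
        for col in ("arm", "subgroup", "outcome"):
            vals = set(df[col].unique().tolist())
            if not vals <= {0, 1}:
                raise ValueError(f"column {col!r} must be 0/1, found {sorted(vals)}")
            df[col] = df[col].astype(np.int64)
        df["weight"] = df["weight"].astype(float)
        if (df["weight"] <= 0).any():
            raise ValueError("weights must be > 0")
        for trial, g in df.groupby("trial"):
            if set(g["arm"].unique()) != {0, 1}:
                raise ValueError(f"trial {trial}: needs both arms")
        object.__setattr__(self, "data", df[list(IPD_COLUMNS)].reset_index(drop=True))

    @property
    def total_weight(self) -> float:
        return float(self.data["weight"].sum())

    @property
    def trials(self) -> list[str]:
        return sorted(self.data["trial"].unique())

    def restrict(self, stratum: int | str) -> pd.DataFrame:
        """Records of one subgroup stratum (0, 1) or 'all'."""
        if stratum == "all":
            return self.data
        if stratum not in (0, 1):
            raise ValueError(f"stratum must be 0, 1 or 'all', got {stratum!r}")
        return self.data[self.data["subgroup"] == stratum]

    def to_tables(self, stratum: int | str = "all") -> list[TwoByTwoTable]:
        """Collapse (a stratum of) the IPD into per-trial 2x2 tables.

        Trials with no eligible records in either arm are dropped.
        """
        df = self.restrict(stratum)
        tables = []
        for trial in sorted(df["trial"].unique()):
            g = df[df["trial"] == trial]
            n1 = g.loc[g["arm"] == 1, "weight"].sum()
            n0 = g.loc[g["arm"] == 0, "weight"].sum()
            if n1 <= 0 or n0 <= 0:
                continue
            a = g.loc[(g["arm"] == 1) & (g["outcome"] == 1), "weight"].sum()
            c = g.loc[(g["arm"] == 0) & (g["outcome"] == 1), "weight"].sum()
            tables.append(TwoByTwoTable(label=trial, a=a, n1=n1, c=c, n0=n0))
        return tables


@dataclass(frozen=True)
class MHRiskRatio:
    rr: float
    log_variance: float
    stratum: str
    n_trials: int

    @property
    def log_se(self) -> float:
        return math.sqrt(self.log_variance)


def mh_risk_ratio(ipd: IPDDataset, stratum: int | str = "all") -> MHRiskRatio:
    """Mantel-Haenszel risk ratio pooled across trials within a stratum.

    RR_MH = sum_i(a_i n0_i / N_i) / sum_i(c_i n1_i / N_i) over the
    stratum-restricted per-trial tables; the log-RR variance is the
    Greenland-Robins estimator
    sum_i[(n1_i n0_i (a_i + c_i) - a_i c_i N_i) / N_i^2] / (R * S).
    """
    tables = ipd.to_tables(stratum)
    if not tables:
        raise NotEstimableError(f"no eligible trials in stratum {stratum!r}")
    R = sum(t.a * t.n0 / (t.n1 + t.n0) for t in tables)
    S = sum(t.c * t.n1 / (t.n1 + t.n0) for t in tables)
    if R == 0 or S == 0:
        raise NotEstimableError(f"no events in one arm of stratum {stratum!r}")
    P = sum(
        (t.n1 * t.n0 * (t.a + t.c) - t.a * t.c * (t.n1 + t.n0)) / (t.n1 + t.n0) ** 2
        for t in tables
    )
    return MHRiskRatio(
        rr=R / S,
        log_variance=P / (R * S),
        stratum=str(stratum),
        n_trials=len(tables),
    )


@dataclass(frozen=True)
class InteractionFit:
    """A converged weighted logistic fit with trial fixed effects."""

    params: pd.Series
    cov: pd.DataFrame
    loglike: float
    converged: bool
    n_obs: float                  # total weight
    reference_trial: str

    INTERACTION = "treatment:subgroup"

    @property
    def interaction_coef(self) -> float:
        return float(self.params[self.INTERACTION])

    @property
    def interaction_se(self) -> float:
        return float(math.sqrt(self.cov.loc[self.INTERACTION, self.INTERACTION]))


def _design(ipd: IPDDataset, interaction: bool) -> tuple[pd.DataFrame, str]:
    df = ipd.data
    trials = sorted(df["trial"].unique())
    reference = trials[0]
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    for t in trials[1:]:
        X[f"trial[{t}]"] = (df["trial"] == t).astype(float)
    X["treatment"] = df["arm"].astype(float)
    X["subgroup"] = df["subgroup"].astype(float)
    if interaction:
        X["treatment:subgroup"] = X["treatment"] * X["subgroup"]
    return X, reference


def _check_rank(X: pd.DataFrame, w: np.ndarray) -> None:
    # weighted design; name the first redundant column for the error message
    A = X.to_numpy() * np.sqrt(w)[:, None]
    rank = np.linalg.matrix_rank(A)
    if rank == A.shape[1]:
        return
    cols = list(X.columns)
    kept: list[int] = []
    offender = cols[-1]
    for j in range(A.shape[1]):
        if np.linalg.matrix_rank(A[:, kept + [j]]) > len(kept):
            kept.append(j)
        else:
            offender = cols[j]
            break
    raise NonIdentifiableError(f"design matrix is rank deficient: column {offender!r}")


def _aggregate(ipd: IPDDataset) -> pd.DataFrame:
    # identical covariate/outcome rows are pooled by summing weights; the
    # weighted log-likelihood and information are unchanged and fits on
    # per-participant data become O(cells) instead of O(n)
    return (
        ipd.data.groupby(["trial", "arm", "subgroup", "outcome"], as_index=False)[
            "weight"
        ].sum()
    )


def _fit_glm(ipd: IPDDataset, interaction: bool) -> tuple[sm.GLM, object, str]:
    agg = IPDDataset(_aggregate(ipd))
    X, reference = _design(agg, interaction)
    w = agg.data["weight"].to_numpy()
    _check_rank(X, w)
    y = agg.data["outcome"].to_numpy().astype(float)
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    res = model.fit(maxiter=100, tol=1e-10)
    return model, res, reference


def fit_interaction_model(ipd: IPDDataset) -> InteractionFit:
    """Weighted ML logistic fit of outcome ~ trial + treatment * subgroup.

    The first trial in label order is the reference level for the trial
    indicators.  Raises if the design is rank deficient or the optimizer
    fails to converge.
    """
    _, res, reference = _fit_glm(ipd, interaction=True)
    if not res.converged:
        raise NonIdentifiableError("logistic fit did not converge (separation?)")
    params = pd.Series(res.params, index=res.model.exog_names)
    cov = pd.DataFrame(
        res.cov_params(), index=res.model.exog_names, columns=res.model.exog_names
    )
    return InteractionFit(
        params=params,
        cov=cov,
        loglike=float(res.llf),
        converged=bool(res.converged),
        n_obs=ipd.total_weight,
        reference_trial=reference,
    )


def interaction_test(
    fit: InteractionFit,
    method: str = "wald",
    ipd: IPDDataset | None = None,
) -> tuple[float, float]:
    """Test the treatment-by-subgroup interaction coefficient.

    ``wald``: z = beta / se, two-sided normal p-value.
    ``lrt``: 2 * (loglike_full - loglike_reduced), chi-square 1 df; needs
    ``ipd`` to refit the reduced (no interaction) model on the same data.
    """
    if not fit.converged:
        raise NonIdentifiableError("cannot test an unconverged fit")
    if method == "wald":
        z = fit.interaction_coef / fit.interaction_se
        from scipy import stats as _st

        return z, float(2.0 * _st.norm.sf(abs(z)))
    if method == "lrt":
        if ipd is None:
            raise ValueError("the likelihood-ratio test needs the IPD to refit")
        _, reduced, _ = _fit_glm(ipd, interaction=False)
        lr = 2.0 * (fit.loglike - float(reduced.llf))
        lr = max(lr, 0.0)
        from scipy import special as _sp

        return lr, float(_sp.gammaincc(0.5, lr / 2.0))
    raise ValueError(f"unknown test method {method!r}")


def read_ipd_frame(df: pd.DataFrame) -> IPDDataset:
    """Validate a raw DataFrame in the IPD dialect into an IPDDataset."""
    try:
        return IPDDataset(df)
    except ValueError as exc:
        raise InvalidTableError(str(exc)) from exc
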