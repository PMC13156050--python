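"""Group x age moderation with Johnson-Neyman regions of significance.

The model per outcome (a thickness node or a region mean) is OLS:

    y = b0 + b1*X + b2*M + b3*(X*M) + covariates + e

with X the focal predictor (group indicator, 0 = control / 1 = patient, or
a continuous predictor such as region thickness) and M the moderator (age
in years, uncentred).  The conditional effect of X at moderator value M is

    theta(M) = b1 + b3*M,      SE(M) = sqrt(v11 + 2*M*v13 + M^2*v33)

with v.. entries of the coefficient covariance.  The Johnson-Neyman
boundaries are the moderator values where |theta/SE| equals the two-tailed
critical t, obtained in closed form from a quadratic; pointwise scans over
the 100 thickness nodes are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModerationFit",
    "ConditionalEffect",
    "JNSolution",
    "RegionDefinition",
    "WITELSON_REGIONS",
    "fit_moderation",
    "conditional_effect",
    "jn_boundaries",
    "crossover_age",
    "pointwise_scan",
    "aggregate_regions",
    "bh_fdr",
]


@dataclass
class ModerationFit:
    """OLS coefficients and covariance for the interaction model."""

    params: pd.Series  # const, predictor, moderator, interaction, covariates...
    cov: pd.DataFrame
    df_resid: int
    n: int
    predictor: str
    moderator: str

    @property
    def b1(self) -> float:
        return float(self.params[self.predictor])

    @property
    def b3(self) -> float:
        return float(self.params[self._ix])

    @property
    def _ix(self) -> str:
        return f"{self.predictor}:{self.moderator}"

    @property
    def v11(self) -> float:
        return float(self.cov.loc[self.predictor, self.predictor])

    @property
    def v13(self) -> float:
        return float(self.cov.loc[self.predictor, self._ix])

    @property
    def v33(self) -> float:
        return float(self.cov.loc[self._ix, self._ix])


@dataclass
class ConditionalEffect:
    moderator_value: np.ndarray
    theta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    alpha: float


@dataclass
class JNSolution:
    """Regions of significance of the conditional effect over the moderator."""

    boundaries: list[float]  # 0, 1 or 2 ages inside the observed range
    intervals: list[tuple[float, float, str]]  # (lo, hi, label)
    alpha: float
    moderator_range: tuple[float, float]
    t_crit: float

    def significant_anywhere(self) -> bool:
        return any(lab != "ns" for _, _, lab in self.intervals)


@dataclass(frozen=True)
class RegionDefinition:
    """Inclusive node window anchored on the Witelson subdivision."""

    region_id: str
    start: int
    end: int
    label: str

    @property
    def nodes(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


#: callosal regions used for follow-up analyses: streamline windows anchored
#: on the Witelson subdivision (rostral body, anterior midbody + posterior
#: rostral body, isthmus, splenium)
WITELSON_REGIONS: tuple[RegionDefinition, ...] = (
    RegionDefinition("I", 73, 78, "rostral body (anterior half of Witelson 3)"),
    RegionDefinition("II", 51, 72, "anterior midbody + posterior rostral body"),
    RegionDefinition("III", 24, 32, "isthmus (Witelson 6)"),
    RegionDefinition("IV", 13, 23, "splenium (Witelson 7)"),
)


def _design_matrix(
    predictor: np.ndarray,
    moderator: np.ndarray,
    covariates: pd.DataFrame | None,
    predictor_name: str,
    moderator_name: str,
) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "const": np.ones(len(predictor)),
            predictor_name: predictor,
            moderator_name: moderator,
            f"{predictor_name}:{moderator_name}": predictor * moderator,
        }
    )
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
    return X


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    _, s, vt = np.linalg.svd(np.asarray(X, dtype=float), full_matrices=False)
    null = vt[s < s.max() * 1e-8]
    if not len(null):
        null = vt[-1:]
    weights = np.abs(null).max(axis=0)
    return list(X.columns[weights > 0.1 * weights.max()])


def fit_moderation(
    outcome,
    predictor,
    moderator,
    covariates: pd.DataFrame | None = None,
    predictor_name: str = "group",
    moderator_name: str = "age",
) -> ModerationFit:
    """Fit the interaction model by OLS and return coefficients + covariance.

    Rows with missing values in any variable are dropped (with a warning
    carrying the count).  A rank-deficient design raises ``ValueError``
    naming the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    m = np.asarray(moderator, dtype=float)
    X = _design_matrix(x, m, covariates, predictor_name, moderator_name)
    ok = np.isfinite(y) & np.isfinite(np.asarray(X)).all(axis=1)
    if (~ok).any():
        warnings.warn(f"dropping {int((~ok).sum())} rows with missing values")
        y, X = y[ok], X.loc[ok]
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} complete rows, got {n}")
    Xv = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(Xv) < k:
        raise ValueError(
            f"rank-deficient design; collinear columns: {_collinear_columns(X)}"
        )
    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    return ModerationFit(
        params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        df_resid=int(res.df_resid),
        n=n,
        predictor=predictor_name,
        moderator=moderator_name,
    )


def conditional_effect(
    fit: ModerationFit, M, alpha: float = 0.05
) -> ConditionalEffect:
    """theta(M), its standard error, t, two-tailed p and CI at ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    M = np.atleast_1d(np.asarray(M, dtype=float))
    if not np.isfinite(M).all():
        raise ValueError("moderator values must be finite")
    theta = fit.b1 + fit.b3 * M
    var = fit.v11 + 2 * M * fit.v13 + M**2 * fit.v33
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, theta / se, np.inf * np.sign(theta))
    p = 2 * stats.t.sf(np.abs(t), fit.df_resid)
    tc = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    return ConditionalEffect(
        moderator_value=M,
        theta=theta,
        se=se,
        t=t,
        p=p,
        ci_low=theta - tc * se,
        ci_high=theta + tc * se,
        alpha=alpha,
    )


def jn_boundaries(
    fit: ModerationFit,
    alpha: float = 0.05,
    moderator_range: tuple[float, float] | None = None,
) -> JNSolution:
    """Closed-form Johnson-Neyman boundaries within the moderator range.

    Solves (tc^2 v33 - b3^2) M^2 + 2 (tc^2 v13 - b1 b3) M + (tc^2 v11 - b1^2)
    = 0 and keeps real roots inside the range; each interval between
    consecutive boundaries is labelled 'negative', 'ns' or 'positive' from
    the conditional effect at its midpoint.
    """
    if moderator_range is None or moderator_range[0] >= moderator_range[1]:
        raise ValueError("moderator_range (low, high) with low < high is required")
    lo, hi = map(float, moderator_range)
    tc = float(stats.t.ppf(1 - alpha / 2, fit.df_resid))
    a = tc**2 * fit.v33 - fit.b3**2
    b = 2 * (tc**2 * fit.v13 - fit.b1 * fit.b3)
    c = tc**2 * fit.v11 - fit.b1**2
    roots: list[float] = []
    if abs(a) < 1e-300:
        if abs(b) > 0:
            roots = [-c / b]
    else:
        disc = b**2 - 4 * a * c
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    roots = sorted(r for r in roots if lo < r < hi)
    edges = [lo] + roots + [hi]
    intervals = []
    for a_, b_ in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a_ + b_)
        eff = conditional_effect(fit, mid, alpha)
        if abs(eff.t[0]) > tc:
            label = "positive" if eff.theta[0] > 0 else "negative"
        else:
            label = "ns"
        intervals.append((a_, b_, label))
    return JNSolution(
        boundaries=roots,
        intervals=intervals,
        alpha=alpha,
        moderator_range=(lo, hi),
        t_crit=tc,
    )


def crossover_age(fit: ModerationFit) -> float:
    """Moderator value where the conditional effect crosses zero."""
    if fit.b3 == 0:
        return np.nan
    return -fit.b1 / fit.b3


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def pointwise_scan(
    profiles: pd.DataFrame,
    group,
    age,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-node group x age interaction scan with BH-FDR over the nodes.

    ``profiles`` has one row per subject and one column per node.  All
    nodes share the same design matrix, so a single least-squares solve
    with multiple right-hand sides fits all nodes at once.  Returns a frame
    indexed by node with the interaction estimate, its SE, t, p, BH q and
    the q <= alpha significance mask.
    """
    g = np.asarray(group, dtype=float)
    m = np.asarray(age, dtype=float)
    X = _design_matrix(g, m, covariates, "group", "age")
    Y = np.asarray(profiles, dtype=float)
    if len(Y) != len(X):
        raise ValueError("profiles and cohort tables are not row-aligned")
    ok = np.isfinite(Y).all(axis=1) & np.isfinite(np.asarray(X)).all(axis=1)
    if (~ok).any():
        warnings.warn(f"dropping {int((~ok).sum())} rows with missing values")
        Y, X = Y[ok], X.loc[ok]
    Xv = np.asarray(X, dtype=float)
    n, k = Xv.shape
    if np.linalg.matrix_rank(Xv) < k:
        raise ValueError(
            f"rank-deficient design; collinear columns: {_collinear_columns(X)}"
        )
    xtx_inv = np.linalg.inv(Xv.T @ Xv)
    beta = xtx_inv @ Xv.T @ Y  # (k, nodes)
    resid = Y - Xv @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    j = list(X.columns).index("group:age")
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    t = beta[j] / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "b_interaction": beta[j],
            "se": se,
            "t": t,
            "p": p,
            "q": q,
            "significant": q <= alpha,
        },
        index=pd.Index(profiles.columns, name="node"),
    )


def aggregate_regions(
    profiles: pd.DataFrame,
    regions: tuple[RegionDefinition, ...] = WITELSON_REGIONS,
) -> pd.DataFrame:
    """Per-subject arithmetic mean thickness within each region window."""
    out = {}
    ncol = profiles.shape[1]
    for reg in regions:
        if reg.start > reg.end:
            raise ValueError(f"region {reg.region_id} has an empty node window")
        if reg.start < 0 or reg.end >= ncol:
            raise ValueError(
                f"region {reg.region_id} window {reg.start}..{reg.end} outside 0..{ncol - 1}"
            )
        out[reg.region_id] = profiles.iloc[:, reg.start : reg.end + 1].mean(axis=1)
    return pd.DataFrame(out, index=profiles.index)
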