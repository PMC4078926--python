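"""Group-level statistics for the case-control battery.

Covers the analysis chain applied to the subject table: normalizing
transforms (square root and log, with reflection for reversed measures),
independent two-sample t-tests computable from summary statistics alone,
Bonferroni adjustment capped at 1, ANCOVA of the group effect with partial
eta-squared, Pearson and group-partialled correlation matrices, and
fixed-order hierarchical regressions reporting R-squared change and
standardized betas per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "TransformResult",
    "apply_transform",
    "TRANSFORM_KINDS",
    "TTestResult",
    "independent_t",
    "bonferroni",
    "AncovaResult",
    "ancova_group_effect",
    "correlation_matrix",
    "RegressionStep",
    "RegressionReport",
    "hierarchical_regression",
]

TRANSFORM_KINDS = ("none", "sqrt", "reflect_then_sqrt", "reflect_then_log")


@dataclass(frozen=True)
class TransformResult:
    values: np.ndarray
    kind: str
    reflect_constant: float | None = None

    def invert(self) -> np.ndarray:
        """Recover the original values from the stored constant."""
        v = np.asarray(self.values, dtype=float)
        if self.kind == "none":
            return v.copy()
        if self.kind == "sqrt":
            return v**2
        if self.kind == "reflect_then_sqrt":
            return self.reflect_constant - v**2
        if self.kind == "reflect_then_log":
            return self.reflect_constant - np.exp(v)
        raise ConfigurationError(f"unknown transform kind {self.kind!r}")


def apply_transform(
    values, kind: str, reflect_constant: float | None = None
) -> TransformResult:
    """Apply a normalizing transform.

    ``reflect_then_*`` first reflects about the sample maximum plus one
    (x -> max(x)+1-x, reversing the order of subjects) and then applies the
    named function; the reflection constant is stored for invertibility.
    Raises when a non-positive value would enter sqrt or log, naming the
    offending position.
    """
    v = np.asarray(values, dtype=float)
    if kind not in TRANSFORM_KINDS:
        raise ConfigurationError(f"unknown transform kind {kind!r}")
    if kind == "none":
        return TransformResult(v.copy(), kind)
    if kind == "sqrt":
        _check_positive(v, "sqrt")
        return TransformResult(np.sqrt(v), kind)
    const = float(np.nanmax(v) + 1.0) if reflect_constant is None else float(reflect_constant)
    refl = const - v
    if kind == "reflect_then_sqrt":
        _check_positive(refl, "sqrt")
        return TransformResult(np.sqrt(refl), kind, const)
    _check_positive(refl, "log")
    return TransformResult(np.log(refl), kind, const)


def _check_positive(v: np.ndarray, fn: str) -> None:
    bad = np.where(~(v > 0))[0]
    if bad.size:
        raise ConfigurationError(
            f"non-positive value at position {int(bad[0])} would enter {fn}"
        )


# --------------------------------------------------------------------------
# t-tests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def independent_t(group_a, group_b, variant: str = "pooled") -> TTestResult:
    """Independent two-sample t-test, pooled or Welch.

    Each group is either a raw 1-D sample or a ``(mean, sd, n)`` summary
    triple; raw data are reduced to their summaries first, so the two input
    forms agree to machine precision.
    """
    ma, sa, na = _summary(group_a)
    mb, sb, nb = _summary(group_b)
    if na < 2 or nb < 2:
        raise ConfigurationError("each group needs n >= 2")
    if sa == 0.0 and sb == 0.0 and ma == mb:
        return TTestResult(0.0, na + nb - 2 if variant == "pooled" else na + nb - 2, 1.0, variant)
    if variant == "pooled":
        sp2 = ((na - 1) * sa**2 + (nb - 1) * sb**2) / (na + nb - 2)
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2.0
    elif variant == "welch":
        va, vb = sa**2 / na, sb**2 / nb
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    else:
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    t = (ma - mb) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), variant)


def _summary(g) -> tuple[float, float, int]:
    if isinstance(g, (tuple, list)) and len(g) == 3 and np.isscalar(g[0]):
        m, s, n = g
        if s < 0:
            raise ConfigurationError("SD must be non-negative")
        return float(m), float(s), int(n)
    arr = np.asarray(g, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: multiply p by the number of comparisons per
    question, capped at 1."""
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError("p must lie in [0, 1]")
    if m < 1:
        raise ConfigurationError("number of comparisons must be >= 1")
    return min(1.0, p * m)


# --------------------------------------------------------------------------
# ANCOVA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AncovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float
    degenerate: bool = False


def ancova_group_effect(
    data: pd.DataFrame,
    y: str,
    group: str,
    covariates: list[str],
) -> AncovaResult:
    """Group effect on ``y`` adjusted for covariates in a linear model.

    F compares the full model (covariates + group) with the reduced model
    (covariates only); partial eta-squared is SS_effect/(SS_effect+SS_error)
    from the full model.  Collinear covariates raise with a condition-number
    diagnostic; a covariate (near-)identical to y is flagged degenerate.
    """
    d = data[[y, group] + covariates].dropna()
    levels = d[group].unique()
    if len(levels) != 2:
        raise ConfigurationError(f"group column must have 2 levels, found {len(levels)}")
    g = (d[group] == levels[0]).astype(float).to_numpy()
    X_cov = sm.add_constant(d[covariates].to_numpy(dtype=float), has_constant="add")
    cond = np.linalg.cond(X_cov)
    if cond > 1e10:
        raise ConfigurationError(
            f"collinear covariates (condition number {cond:.3g})"
        )
    yv = d[y].to_numpy(dtype=float)
    red = sm.OLS(yv, X_cov).fit()
    X_full = np.column_stack([X_cov, g])
    full = sm.OLS(yv, X_full).fit()
    ss_err = float(full.ssr)
    ss_eff = float(red.ssr - full.ssr)
    df_eff = 1
    df_err = int(full.df_resid)
    degenerate = ss_err + ss_eff < 1e-12 * max(1.0, float(np.var(yv)) * len(yv))
    if degenerate:
        return AncovaResult(float("nan"), df_eff, df_err, float("nan"), float("nan"), True)
    F = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(stats.f.sf(F, df_eff, df_err))
    eta = ss_eff / (ss_eff + ss_err)
    return AncovaResult(float(F), df_eff, df_err, p, float(eta), False)


# --------------------------------------------------------------------------
# Correlations
# --------------------------------------------------------------------------

def correlation_matrix(
    data: pd.DataFrame,
    control_for_group: bool = False,
    groups: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    With ``control_for_group`` on, each pair is the partial correlation
    given the binary group indicator: both variables are residualized on
    the indicator and the residuals correlated, with p from a t statistic
    on n-3 degrees of freedom.  Constant columns raise.
    """
    cols = list(data.columns)
    d = data.dropna()
    for c in cols:
        if float(d[c].std(ddof=1)) == 0.0:
            raise ConfigurationError(f"constant column {c!r}: correlation undefined")
    if control_for_group:
        if groups is None:
            raise ConfigurationError("control_for_group requires a groups series")
        g = groups.reindex(d.index)
        gv = (g == g.unique()[0]).astype(float).to_numpy()
        X = sm.add_constant(gv)
        resid = {c: sm.OLS(d[c].to_numpy(dtype=float), X).fit().resid for c in cols}
        d = pd.DataFrame(resid, index=d.index)
        df_t = len(d) - 3
    else:
        df_t = len(d) - 2
    if df_t < 1:
        raise ConfigurationError("need at least 3 complete observations per pair")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            rij = float(np.corrcoef(d[ci], d[cj])[0, 1])
            tstat = rij * math.sqrt(df_t / max(1e-300, 1.0 - rij**2))
            pij = 2.0 * stats.t.sf(abs(tstat), df_t)
            r.loc[ci, cj] = r.loc[cj, ci] = rij
            p.loc[ci, cj] = p.loc[cj, ci] = pij
    return r, p


# --------------------------------------------------------------------------
# Hierarchical regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionStep:
    predictors: tuple[str, ...]
    r_squared: float
    r_squared_change: float
    betas: dict[str, float]
    F: float
    df_model: int
    df_resid: int
    p: float


@dataclass(frozen=True)
class RegressionReport:
    y: str
    covariates: tuple[str, ...]
    steps: tuple[RegressionStep, ...] = field(default_factory=tuple)


def hierarchical_regression(
    data: pd.DataFrame,
    y: str,
    step_blocks: list[list[str]],
    covariates: list[str] | None = None,
) -> RegressionReport:
    """Fixed-order hierarchical OLS.

    Variables are z-scored on the listwise-complete analysis sample, so the
    reported betas are standardized.  Covariates (if any) form step 0; each
    block then enters cumulatively, and the step's R-squared change is the
    increment over the previous step.  Singular designs raise.
    """
    covariates = covariates or []
    all_vars = [y] + covariates + [v for b in step_blocks for v in b]
    d = data[list(dict.fromkeys(all_vars))].dropna()
    if len(d) <= len(all_vars):
        raise ConfigurationError("too few complete cases for the design")
    z = (d - d.mean()) / d.std(ddof=1)
    if z.isna().any().any():
        raise ConfigurationError("constant variable in design")

    def fit(preds: list[str]):
        X = sm.add_constant(z[preds].to_numpy(dtype=float), has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ConfigurationError(f"singular design with predictors {preds}")
        return sm.OLS(z[y].to_numpy(dtype=float), X).fit()

    steps = []
    cumulative = list(covariates)
    prev_r2 = 0.0
    if covariates:
        res = fit(cumulative)
        prev_r2 = float(res.rsquared)
        steps.append(_step(res, cumulative, prev_r2, prev_r2))
    for block in step_blocks:
        cumulative = cumulative + list(block)
        res = fit(cumulative)
        r2 = float(res.rsquared)
        steps.append(_step(res, cumulative, r2, r2 - prev_r2))
        prev_r2 = r2
    return RegressionReport(y=y, covariates=tuple(covariates), steps=tuple(steps))


def _step(res, preds: list[str], r2: float, dr2: float) -> RegressionStep:
    betas = {name: float(res.params[k + 1]) for k, name in enumerate(preds)}
    return RegressionStep(
        predictors=tuple(preds),
        r_squared=r2,
        r_squared_change=dr2,
        betas=betas,
        F=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        p=float(res.f_pvalue),
    )
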