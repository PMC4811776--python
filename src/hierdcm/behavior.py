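"""Individual-difference statistics: factors, correlations, RT gradients.

Connectivity-modulation estimates and trait ability tests are distilled
into single factors (first principal component, sign-aligned so that a
higher score means more of the measured quantity), related by Pearson
correlation supplemented with Huber robust regression, and by partial
correlations on residuals.  The reaction-time gradient analysis regresses
Current RT (sub-task trials) and Future RT (return trials) on zone-wise
activation within each subject and performs group statistics on the
slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.anova import AnovaRM

ZONE_ORDER = ("caudal", "mid", "rostral")


def zscore_within_subject(values) -> np.ndarray | pd.DataFrame:
    """Z-score each subject's row across conditions (mean 0, sd 1, ddof=1).

    Removes between-subject offsets so that condition effects are
    comparable across subjects.  Raises if any subject has fewer than two
    conditions or zero variance.
    """
    df = pd.DataFrame(values)
    if df.shape[1] < 2:
        raise ValueError("within-subject z-scoring needs at least 2 conditions")
    sd = df.std(axis=1, ddof=1)
    bad = sd[sd == 0]
    if len(bad):
        raise ValueError(f"zero within-subject variance for subject(s) {list(bad.index)}")
    z = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    return z if isinstance(values, pd.DataFrame) else z.to_numpy()


@dataclass
class FactorScores:
    """First-principal-component scores over a standardized measure set."""

    scores: np.ndarray
    loadings: np.ndarray
    variables: list[str]
    explained_variance_ratio: float
    flipped: bool
    dropped: list[str] = field(default_factory=list)


def first_eigenvariate_factor(measures, align_with: np.ndarray | None = None) -> FactorScores:
    """First eigenvariate of a subjects x variables table.

    Columns are standardized before the decomposition; constant columns
    are dropped with a warning.  The sign convention makes the result
    deterministic: loadings are flipped so their sum (or, if supplied, the
    correlation of scores with ``align_with``) is positive — higher scores
    mean more of the measured quantity.
    """
    df = pd.DataFrame(measures)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    sd = df.std(axis=0, ddof=1)
    dropped = [str(c) for c in df.columns[sd == 0]]
    if dropped:
        warnings.warn(f"dropping constant column(s) {dropped}", RuntimeWarning)
        df = df.loc[:, sd != 0]
    if df.shape[1] == 0:
        raise ValueError("no non-constant variables left")
    Z = (df - df.mean(axis=0)) / df.std(axis=0, ddof=1)
    Z = Z.to_numpy()
    # first right singular vector = first PC loadings (unit norm)
    _, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[0]
    scores = Z @ loadings
    flipped = False
    if align_with is not None:
        flip = np.corrcoef(scores, align_with)[0, 1] < 0
    else:
        s = loadings.sum()
        flip = s < 0 or (s == 0 and loadings[0] < 0)
    if flip:
        loadings = -loadings
        scores = -scores
        flipped = True
    evr = float(svals[0] ** 2 / np.sum(svals**2))
    return FactorScores(
        scores=scores,
        loadings=loadings,
        variables=[str(c) for c in df.columns],
        explained_variance_ratio=evr,
        flipped=flipped,
        dropped=dropped,
    )


@dataclass
class CorrelationResult:
    r: float
    p: float
    robust_slope: float
    robust_t: float
    robust_p: float
    n: int


def correlate_factors(x, y) -> CorrelationResult:
    """Pearson correlation plus Huber robust regression of y on x.

    The robust fit (IRLS, Huber weights, tuning constant 1.345) reduces
    the impact of high-leverage outliers; both are reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    X = sm.add_constant(x)
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
    return CorrelationResult(
        r=float(r),
        p=float(p),
        robust_slope=float(rlm.params[1]),
        robust_t=float(rlm.tvalues[1]),
        robust_p=float(rlm.pvalues[1]),
        n=int(x.size),
    )


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x,
    y,
    controls=None,
    subject_ids=None,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation of x and y after regressing out controls from both.

    ``controls`` is an (n, k) array (or None); ``subject_ids`` adds
    subject dummy variables to the control set.  Returns (rho, p) with
    degrees of freedom reduced by the number of regressors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    cols = [np.ones(n)]
    k = 0
    if controls is not None:
        Cm = np.atleast_2d(np.asarray(controls, dtype=float))
        if Cm.shape[0] != n:
            Cm = Cm.T
        for j in range(Cm.shape[1]):
            cols.append(Cm[:, j])
            k += 1
    if subject_ids is not None:
        dummies = pd.get_dummies(pd.Series(subject_ids), drop_first=True).to_numpy(dtype=float)
        for j in range(dummies.shape[1]):
            cols.append(dummies[:, j])
            k += 1
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear controls")
    if n <= k + 2:
        raise ValueError("need n > #controls + 2")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if method == "pearson":
        rho = np.corrcoef(rx, ry)[0, 1]
    elif method == "spearman":
        rho = stats.spearmanr(rx, ry).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - k - 2
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt(df / max(1e-300, 1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


@dataclass
class GradientResult:
    """RT-gradient analysis outputs."""

    slopes: pd.DataFrame  # long: subject, zone, time, slope
    anova: pd.DataFrame  # 3x2 repeated-measures ANOVA on the slopes
    interaction_F: float
    interaction_p: float
    partials: pd.DataFrame  # pooled partial correlations per zone x time
    collinear: bool


def _simple_slope(x: np.ndarray, yv: np.ndarray) -> float:
    vx = np.var(x)
    if vx == 0:
        return np.nan
    return float(np.cov(x, yv, ddof=1)[0, 1] / np.var(x, ddof=1))


def rt_gradient_analysis(
    activations: np.ndarray,
    current_rt: np.ndarray,
    future_rt: np.ndarray,
    zones: tuple[str, ...] = ZONE_ORDER,
) -> GradientResult:
    """Temporal activation-behavior gradient across LPFC zones.

    ``activations`` is (subjects, conditions, zones); RT inputs are
    (subjects, conditions) and are z-scored within subject.  For each
    subject and zone, Current and Future RT are separately regressed on
    activation; the slopes enter a zone x time repeated-measures ANOVA.
    Pooled partial correlations (controlling the other RT measure, with
    subject dummies) are a secondary output.  Near-identical Current and
    Future RT flags collinearity.
    """
    act = np.asarray(activations, dtype=float)
    if act.ndim != 3 or act.shape[2] != len(zones):
        raise ValueError(f"activations must be (subjects, conditions, {len(zones)} zones)")
    n_sub, n_cond, _ = act.shape
    cur = np.asarray(zscore_within_subject(current_rt))
    fut = np.asarray(zscore_within_subject(future_rt))
    if cur.shape != (n_sub, n_cond) or fut.shape != (n_sub, n_cond):
        raise ValueError("RT tables must match activations in subjects and conditions")

    rows = []
    for s in range(n_sub):
        for zi, zone in enumerate(zones):
            a = act[s, :, zi]
            rows.append((s, zone, "current", _simple_slope(a, cur[s])))
            rows.append((s, zone, "future", _simple_slope(a, fut[s])))
    slopes = pd.DataFrame(rows, columns=["subject", "zone", "time", "slope"])
    if slopes["slope"].isna().any():
        raise ValueError("zero activation variance for some subject/zone")

    anova = AnovaRM(slopes, "slope", "subject", within=["zone", "time"]).fit().anova_table
    inter = anova.loc["zone:time"]

    r_cf = np.corrcoef(cur.ravel(), fut.ravel())[0, 1]
    collinear = bool(abs(r_cf) > 0.999)
    subj = np.repeat(np.arange(n_sub), n_cond)
    prow = []
    for zi, zone in enumerate(zones):
        a = act[:, :, zi].ravel()
        if collinear:
            prow.append((zone, "current", np.nan, np.nan))
            prow.append((zone, "future", np.nan, np.nan))
            continue
        rho_c, p_c = partial_correlation(a, cur.ravel(), controls=fut.ravel(), subject_ids=subj)
        rho_f, p_f = partial_correlation(a, fut.ravel(), controls=cur.ravel(), subject_ids=subj)
        prow.append((zone, "current", rho_c, p_c))
        prow.append((zone, "future", rho_f, p_f))
    partials = pd.DataFrame(prow, columns=["zone", "time", "rho", "p"])
    if collinear:
        warnings.warn("Current and Future RT are collinear; partials undefined", RuntimeWarning)

    return GradientResult(
        slopes=slopes,
        anova=anova,
        interaction_F=float(inter["F Value"]),
        interaction_p=float(inter["Pr > F"]),
        partials=partials,
        collinear=collinear,
    )


def ability_regression(
    topdown,
    bottomup,
    hier,
    ability,
    exclude_low_ability: bool = False,
) -> pd.DataFrame:
    """Simultaneous regression of trait ability on the three connectivity factors.

    Ordinary least squares and Huber robust fits of
    ``ability ~ topdown + bottomup + hierarchical strength``; optionally
    refit after excluding subjects more than 2 SD below mean ability.
    """
    X = np.column_stack([np.asarray(v, dtype=float) for v in (topdown, bottomup, hier)])
    y = np.asarray(ability, dtype=float)
    if X.shape[0] != y.size or y.size < 6:
        raise ValueError("need matched samples with n >= 6")
    if exclude_low_ability:
        keep = y >= y.mean() - 2.0 * y.std(ddof=1)
        X, y = X[keep], y[keep]
    names = ["topdown", "bottomup", "hierarchical"]
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(3)
            for j in range(i + 1, 3)
            if abs(corr[i, j]) > 1.0 - 1e-10
        ]
        raise ValueError(f"rank-deficient predictors; collinear: {pairs or 'with intercept'}")
    ols = sm.OLS(y, Xc).fit()
    rlm = sm.RLM(y, Xc, M=sm.robust.norms.HuberT(t=1.345)).fit()
    return pd.DataFrame(
        {
            "coef": ols.params[1:],
            "t": ols.tvalues[1:],
            "p": ols.pvalues[1:],
            "robust_coef": rlm.params[1:],
            "robust_t": rlm.tvalues[1:],
            "robust_p": rlm.pvalues[1:],
        },
        index=names,
    )
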