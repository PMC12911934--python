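"""Group contrasts, correlations, linear models, and PERMANOVA.

The comparative layer relating FRed to environmental drivers: two-sided
Wilcoxon rank-sum tests with Cliff's delta effect sizes, Pearson
correlation, OLS models with a collinearity pre-screen, and a permutation
PERMANOVA on sample dissimilarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from magfred.exceptions import UndefinedStatisticError, ValidationError

logger = logging.getLogger(__name__)

EXACT_MAX_N = 20


@dataclass(frozen=True)
class GroupContrast:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # Wilcoxon rank-sum W of group a
    p: float
    delta: float  # Cliff's delta, positive when group a tends larger


@dataclass(frozen=True)
class ModelFit:
    response: str
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    term_p: dict[str, float]
    r2: float
    adjusted_r2: float
    f_stat: float
    p: float
    dropped_collinear: tuple[str, ...] = ()
    n: int = 0


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int
    seed: int
    df_model: int
    df_residual: int


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank-sum of ``x`` (midranks for ties).  The p-value is exact for
    n_x + n_y <= 20 without ties and a normal approximation with continuity
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    w = float(scipy.stats.rankdata(pooled)[:n_x].sum())
    if np.all(pooled == pooled[0]):
        return w, 1.0
    method = "exact" if (n_x + n_y <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                   use_continuity=True)
    return w, float(min(res.pvalue, 1.0))


def cliffs_delta(x, y) -> float:
    """Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y).

    Sorted-merge fast path; O((n_x + n_y) log) instead of the O(n_x * n_y)
    pair enumeration, with exact integer arithmetic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    y_sorted = np.sort(y)
    greater = np.searchsorted(y_sorted, x, side="left").sum()   # y_j < x_i
    less = (len(y) - np.searchsorted(y_sorted, x, side="right")).sum()  # y_j > x_i
    return float((int(greater) - int(less)) / (len(x) * len(y)))


def pearson_correlation(x, y) -> tuple[float, float, float]:
    """Pearson product-moment correlation; returns (r, r^2, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need >= 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    res = scipy.stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def _screen_collinear(design: pd.DataFrame, threshold: float) -> tuple[pd.DataFrame, list[str]]:
    """Drop the later column of every numeric pair with |r| > threshold."""
    numeric = [c for c in design.columns if design[c].nunique() > 2]
    dropped: list[str] = []
    for i, a in enumerate(numeric):
        if a in dropped:
            continue
        for b in numeric[i + 1:]:
            if b in dropped:
                continue
            r = np.corrcoef(design[a], design[b])[0, 1]
            if np.isfinite(r) and abs(r) > threshold:
                dropped.append(b)
                logger.warning("collinearity screen: dropping '%s' (|r|=%.3f with '%s')",
                               b, abs(r), a)
    return design.drop(columns=dropped), dropped


def build_design(covariates: pd.DataFrame,
                 reference_levels: dict[str, str] | None = None) -> pd.DataFrame:
    """Dummy-code categorical covariates (stated reference level omitted)."""
    reference_levels = reference_levels or {}
    parts = []
    for col in covariates.columns:
        series = covariates[col]
        if series.dtype.kind in "biufc":
            parts.append(series.astype(float))
        else:
            levels = sorted(series.astype(str).unique())
            ref = reference_levels.get(col, levels[0])
            if ref not in levels:
                raise ValidationError(f"reference level '{ref}' not found in '{col}'")
            for level in levels:
                if level == ref:
                    continue
                parts.append((series.astype(str) == level).astype(float).rename(f"{col}[{level}]"))
    return pd.concat(parts, axis=1)


def fit_fred_model(fred: pd.Series, covariates: pd.DataFrame,
                   reference_levels: dict[str, str] | None = None,
                   collinearity_threshold: float = 0.9) -> ModelFit:
    """OLS of FRed on environmental covariates.

    Categorical covariates are dummy-coded; rows with any missing value are
    excluded listwise; numeric covariates with pairwise |r| above
    ``collinearity_threshold`` are removed (later column dropped) before
    fitting.  Raises on a rank-deficient design after screening.
    """
    design = build_design(covariates, reference_levels)
    frame = pd.concat([fred.rename("__response__"), design], axis=1).dropna()
    # n = terms + 1 is allowed (saturated fit: coefficients exact, F undefined)
    if len(frame) < design.shape[1] + 1:
        raise ValidationError("too few complete observations for the requested terms")
    design = frame.drop(columns="__response__")
    design, dropped = _screen_collinear(design, collinearity_threshold)
    X = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValidationError(f"design matrix rank-deficient after screening (rank {rank}, "
                              f"{X.shape[1]} columns): check {list(design.columns)}")
    fit = sm.OLS(frame["__response__"], X).fit()
    terms = tuple(c for c in X.columns if c != "const")
    with np.errstate(divide="ignore", invalid="ignore"):  # saturated fits -> NaN stats
        return ModelFit(
            response=str(fred.name or "FRed"),
            terms=terms,
            coefficients={c: float(fit.params[c]) for c in X.columns},
            term_p={c: float(fit.pvalues[c]) for c in terms},
            r2=float(fit.rsquared),
            adjusted_r2=float(fit.rsquared_adj),
            f_stat=float(fit.fvalue),
            p=float(fit.f_pvalue),
            dropped_collinear=tuple(dropped),
            n=int(fit.nobs),
        )


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    means = a.mean(axis=0)
    return a - means[:, None] - means[None, :] + a.mean()


def permanova(dist: pd.DataFrame | np.ndarray, design: pd.Series | pd.DataFrame,
              n_permutations: int = 999, seed: int | None = None) -> PermanovaResult:
    """Permutational multivariate ANOVA (pseudo-F on a sample dissimilarity matrix).

    ``design`` is either a single grouping (Series) or a multi-term design
    (DataFrame; categoricals dummy-coded, numerics as-is).  The pseudo-F is
    computed by projecting the Gower-centered squared dissimilarities onto
    the design hat matrix; the p-value is (#{F_perm >= F_obs} + 1) /
    (n_permutations + 1) under random relabeling of samples with a fixed
    seed.
    """
    if seed is None:
        raise ValidationError("permanova requires an explicit seed for reproducibility")
    if isinstance(dist, pd.DataFrame) and hasattr(design, "index"):
        # canonical sample order: results are invariant to input row order
        ids = sorted(map(str, dist.index))
        dist = dist.set_axis(dist.index.astype(str)).set_axis(dist.columns.astype(str), axis=1)
        design = design.set_axis(design.index.astype(str))
        if set(ids) != set(design.index):
            raise ValidationError("design index does not match dissimilarity ids")
        dist = dist.loc[ids, ids]
        design = design.loc[ids]
    d = np.asarray(dist.values if isinstance(dist, pd.DataFrame) else dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("dissimilarity must be square and symmetric")
    if isinstance(design, pd.Series):
        counts = design.value_counts()
        if len(counts) < 2:
            raise ValidationError("PERMANOVA needs at least 2 groups")
        if (counts < 2).any():
            raise ValidationError("every group needs >= 2 members")
        design = design.to_frame()
    if len(design) != n:
        raise ValidationError("design length does not match dissimilarity size")
    X = sm.add_constant(build_design(design), has_constant="add").to_numpy(dtype=float)
    df_model = np.linalg.matrix_rank(X) - 1
    df_resid = n - df_model - 1
    if df_model < 1 or df_resid < 1:
        raise ValidationError("insufficient degrees of freedom for PERMANOVA")

    g = _gower_center(d)
    hat = X @ np.linalg.pinv(X)
    ones = np.full((n, n), 1.0 / n)
    h_model = hat - ones  # projection onto the design space beyond the intercept
    ss_total = float(np.trace(g))

    def ss_model(g_perm: np.ndarray) -> float:
        return float(np.sum(h_model * g_perm))  # tr(H G) for symmetric H

    obs = ss_model(g)
    f_obs = (obs / df_model) / ((ss_total - obs) / df_resid)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if ss_model(g[np.ix_(perm, perm)]) >= obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(obs / ss_total), p=float(p),
                           n_permutations=n_permutations, seed=seed,
                           df_model=int(df_model), df_residual=int(df_resid))


def group_contrast(values: pd.Series, groups: pd.Series,
                   group_a: str, group_b: str) -> GroupContrast:
    """Wilcoxon rank-sum + Cliff's delta contrast of ``values`` between two groups."""
    x = values[groups == group_a].dropna().to_numpy()
    y = values[groups == group_b].dropna().to_numpy()
    w, p = wilcoxon_rank_sum(x, y)
    return GroupContrast(group_a=group_a, group_b=group_b, n_a=len(x), n_b=len(y),
                         statistic=w, p=p, delta=cliffs_delta(x, y))


def community_weighted_mean(table: pd.DataFrame, abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-sample abundance-weighted mean MAG trait vector (samples x traits).

    The default sample dissimilarity input for PERMANOVA on functional trait
    structure: Euclidean distances between these community-weighted means.
    """
    common = [m for m in table.index if m in abundance.columns]
    if not common:
        raise ValidationError("no shared MAGs between trait table and abundance matrix")
    ab = abundance[common].to_numpy(dtype=float)
    totals = ab.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValidationError("sample with zero total abundance")
    weights = ab / totals
    cwm = weights @ table.loc[common].to_numpy(dtype=float)
    return pd.DataFrame(cwm, index=abundance.index, columns=table.columns)
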