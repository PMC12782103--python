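"""Per-feature differential expression for pairwise group contrasts.

Three fitting strategies share one linear-model backbone (cell-means
coding of all response levels, so residual degrees of freedom come from
the full model even when only one pairwise contrast is reported):

* ``de_ols`` — ordinary least squares per feature; inputs are assumed to
  be on log2 scale already, so the difference of group means IS the log2
  fold-change.
* ``de_moderated`` — empirical-Bayes variance moderation: each feature's
  residual variance is shrunk toward a prior variance ``s0^2`` with prior
  degrees of freedom ``d0`` estimated from all features by
  method-of-moments on the log variances, and the t-statistic gains
  ``d0`` degrees of freedom.
* ``de_voom`` — for count matrices: log-CPM transform, a locally-weighted
  mean-variance trend yielding per-observation inverse-variance weights,
  weighted least squares, then the same moderation.

Benjamini-Hochberg adjustment is applied per dataset per contrast; the
step-up implementation here is the single BH used across the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import OmicsMatrix, ResponseSpec

__all__ = [
    "Contrast",
    "DETable",
    "ModerationPrior",
    "benjamini_hochberg",
    "de_ols",
    "de_moderated",
    "de_voom",
    "fit_moderation_prior",
    "trigamma_inverse",
    "voom_weights",
    "volcano_table",
]

VOOM_TREND_SPAN = 0.5  # lowess span for the mean-variance trend
MAX_WEIGHT_RATIO = 1e6


@dataclass(frozen=True)
class Contrast:
    """Pairwise comparison level_a vs level_b (effect oriented a - b)."""

    level_a: str
    level_b: str

    def validate(self, response: ResponseSpec) -> None:
        for lev in (self.level_a, self.level_b):
            if lev not in response.levels:
                raise ValueError(
                    f"contrast level {lev!r} not among response levels "
                    f"{list(response.levels)}"
                )
        if self.level_a == self.level_b:
            raise ValueError("contrast levels must differ")


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes hyperparameters: prior df d0 (may be inf), prior var s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be > 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")

    def posterior_variance(self, s_sq: np.ndarray, d: float) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s_sq, dtype=float), self.s0_sq)
        return (self.d0 * self.s0_sq + d * s_sq) / (self.d0 + d)


@dataclass
class DETable:
    """Per-feature DE results for one contrast on one dataset."""

    table: pd.DataFrame  # feature, log2fc, t, df, p, adj_p, significant
    method: str
    contrast: Contrast
    fdr: float

    def significant_features(self, direction: str | None = None) -> list[str]:
        t = self.table
        mask = t["significant"]
        if direction == "up":
            mask = mask & (t["log2fc"] > 0)
        elif direction == "down":
            mask = mask & (t["log2fc"] < 0)
        return t.loc[mask, "feature"].tolist()


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values.

    adj_(i) = min over j >= i of min(1, m * p_(j) / j), preserving the
    original order of the input vector.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


# ---------------------------------------------------------------------------
# linear-model backbone


def _group_fit(
    Y: np.ndarray,
    labels: np.ndarray,
    levels: list[str],
    contrast: Contrast,
    weights: np.ndarray | None = None,
):
    """(Weighted) cell-means fit of every feature on all response levels.

    Returns effect (a - b), unscaled contrast variance factor v_c,
    residual variance s^2, residual df, and the fitted matrix.
    With weights (n x p), each feature gets its own WLS fit; the group
    design makes the coefficients (weighted) group means.
    """
    n, p = Y.shape
    g = len(levels)
    d = n - g
    if d <= 0:
        raise ValueError(f"zero residual degrees of freedom (n={n}, groups={g})")
    masks = {lev: labels == lev for lev in levels}
    for lev in (contrast.level_a, contrast.level_b):
        if masks[lev].sum() < 2:
            raise ValueError(f"contrast level {lev!r} has fewer than 2 samples")
    if weights is None:
        weights = np.ones_like(Y)
    fitted = np.empty_like(Y)
    wsum = {}
    for lev, mask in masks.items():
        w = weights[mask]
        wsum[lev] = w.sum(axis=0)
        if np.any(wsum[lev] <= 0):
            raise ValueError(f"non-positive weight sum in group {lev!r}")
        fitted[mask] = (w * Y[mask]).sum(axis=0) / wsum[lev]
    resid = Y - fitted
    s_sq = (weights * resid**2).sum(axis=0) / d
    mean_a = fitted[masks[contrast.level_a]][0]
    mean_b = fitted[masks[contrast.level_b]][0]
    effect = mean_a - mean_b
    v_c = 1.0 / wsum[contrast.level_a] + 1.0 / wsum[contrast.level_b]
    return effect, v_c, s_sq, d, fitted


def _assemble_table(
    features: list[str],
    effect: np.ndarray,
    t_stat: np.ndarray,
    df: float,
    p: np.ndarray,
    method: str,
    contrast: Contrast,
    fdr: float,
) -> DETable:
    adj = benjamini_hochberg(p)
    table = pd.DataFrame(
        {
            "feature": features,
            "log2fc": effect,
            "t": t_stat,
            "df": df,
            "p": p,
            "adj_p": adj,
            "significant": adj < fdr,
        }
    )
    return DETable(table=table, method=method, contrast=contrast, fdr=fdr)


def de_ols(
    dataset: OmicsMatrix,
    response: ResponseSpec,
    labels: np.ndarray,
    contrast: Contrast,
    fdr: float = 0.05,
) -> DETable:
    """Ordinary least squares DE; assumes values are already log2-scale."""
    contrast.validate(response)
    effect, v_c, s_sq, d, _ = _group_fit(
        dataset.values, np.asarray(labels).astype(str), list(response.levels), contrast
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(s_sq > 0, effect / np.sqrt(s_sq * v_c), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_stat), d)
    p[(s_sq == 0) & (effect == 0)] = 1.0
    return _assemble_table(
        dataset.feature_ids, effect, t_stat, float(d), p, "ols", contrast, fdr
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the iteration below converges globally
    from the starting value 0.5 + 1/y.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_moderation_prior(s_sq: np.ndarray, d: float) -> ModerationPrior:
    """Method-of-moments fit of (d0, s0^2) from per-feature variances.

    With e_g = log(s_g^2) - psi(d/2) + log(d/2):
    the excess spread var(e) - psi'(d/2) determines d0 via
    psi'(d0/2) = excess (trigamma inversion); no excess means d0 = inf.
    Then s0^2 = exp(mean(e) + psi(d0/2) - log(d0/2)) (geometric-mean
    limit when d0 is infinite).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if len(s_sq) < 10:
        raise ValueError("need >= 10 features to estimate the prior")
    if d < 1:
        raise ValueError("residual df must be >= 1")
    if np.any(s_sq <= 0):
        raise ValueError("residual variances must be positive")
    e = np.log(s_sq) - float(special.digamma(d / 2)) + np.log(d / 2)
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2))
    if excess <= 0:
        # no excess spread: prior df infinite, prior variance the geometric
        # mean of the observed variances (all features share one variance)
        return ModerationPrior(d0=np.inf, s0_sq=float(np.exp(np.mean(np.log(s_sq)))))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(
        np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
    )
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def _moderated_table(
    features: list[str],
    effect: np.ndarray,
    v_c: np.ndarray | float,
    s_sq: np.ndarray,
    d: float,
    prior: ModerationPrior,
    method: str,
    contrast: Contrast,
    fdr: float,
) -> DETable:
    s_tilde_sq = prior.posterior_variance(s_sq, d)
    t_stat = effect / np.sqrt(s_tilde_sq * v_c)
    df_total = prior.d0 + d
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    return _assemble_table(
        features, effect, t_stat, float(df_total), p, method, contrast, fdr
    )


def de_moderated(
    dataset: OmicsMatrix,
    response: ResponseSpec,
    labels: np.ndarray,
    contrast: Contrast,
    fdr: float = 0.05,
    prior: ModerationPrior | None = None,
) -> DETable:
    """Moderated-t DE with empirical-Bayes variance shrinkage."""
    contrast.validate(response)
    effect, v_c, s_sq, d, _ = _group_fit(
        dataset.values, np.asarray(labels).astype(str), list(response.levels), contrast
    )
    if prior is None:
        prior = fit_moderation_prior(s_sq, d)
    return _moderated_table(
        dataset.feature_ids, effect, v_c, s_sq, d, prior, "moderated", contrast, fdr
    )


def voom_weights(
    counts: OmicsMatrix,
    response: ResponseSpec,
    labels: np.ndarray,
    span: float = VOOM_TREND_SPAN,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-CPM transform and mean-variance precision weights for counts.

    The square root of each feature's residual standard deviation is
    smoothed against its mean log2-count by locally-weighted regression;
    each observation's predicted log2-count is mapped through the trend
    (piecewise-linear, flat beyond the range) and the weight is the
    fourth inverse power of the interpolated value, capped so the
    max/min weight ratio stays within 1e6.
    """
    if not counts.is_count:
        raise ValueError(f"dataset {counts.name!r} is not a count matrix")
    C = counts.values
    n, p = C.shape
    if p < 10:
        raise ValueError("need >= 10 features to fit the mean-variance trend")
    lib = C.sum(axis=1)
    if np.any(lib <= 0):
        raise ValueError(f"all-zero sample(s): {np.flatnonzero(lib <= 0).tolist()}")
    logcpm = np.log2((C + 0.5) / (lib + 1.0)[:, None] * 1e6)

    labels = np.asarray(labels).astype(str)
    levels = list(response.levels)
    g = len(levels)
    d = n - g
    if d <= 0:
        raise ValueError("zero residual degrees of freedom")
    fitted = np.empty_like(logcpm)
    for lev in levels:
        mask = labels == lev
        fitted[mask] = logcpm[mask].mean(axis=0)
    resid = logcpm - fitted
    sd = np.sqrt((resid**2).sum(axis=0) / d)
    sqrt_sd = np.sqrt(sd)

    mean_log_lib = float(np.mean(np.log2(lib + 1.0)))
    xbar = logcpm.mean(axis=0) + mean_log_lib - np.log2(1e6)
    trend = lowess(sqrt_sd, xbar, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    tx, keep = np.unique(tx, return_index=True)
    ty = ty[keep]

    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[:, None]
    interp = np.interp(fitted_logcount, tx, ty)  # flat extrapolation
    w = interp**-4.0
    lo = w.min()
    if w.max() / lo > MAX_WEIGHT_RATIO:
        w = np.minimum(w, lo * MAX_WEIGHT_RATIO)
    return logcpm, w


def de_voom(
    counts: OmicsMatrix,
    response: ResponseSpec,
    labels: np.ndarray,
    contrast: Contrast,
    fdr: float = 0.05,
    span: float = VOOM_TREND_SPAN,
) -> DETable:
    """Precision-weighted DE for counts: log-CPM WLS + variance moderation."""
    contrast.validate(response)
    logcpm, w = voom_weights(counts, response, labels, span=span)
    effect, v_c, s_sq, d, _ = _group_fit(
        logcpm, np.asarray(labels).astype(str), list(response.levels), contrast,
        weights=w,
    )
    prior = fit_moderation_prior(s_sq, d)
    return _moderated_table(
        counts.feature_ids, effect, v_c, s_sq, d, prior, "voom", contrast, fdr
    )


def volcano_table(de: DETable, fdr: float) -> pd.DataFrame:
    """Volcano-plot table at a new FDR threshold, without re-fitting."""
    if not (0 <= fdr <= 1):
        raise ValueError("fdr must lie in [0, 1]")
    t = de.table
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(t["p"].to_numpy())
    return pd.DataFrame(
        {
            "feature": t["feature"],
            "log2fc": t["log2fc"],
            "neg_log10_p": neg_log10,
            "significant": t["adj_p"].to_numpy() < fdr,
        }
    )
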