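"""Late-integration biomarker discovery via per-dataset elastic-net ensembles.

One binary classifier is tuned per omics dataset by repeated, seeded,
stratified cross-validation over a user grid of elastic-net penalties
(mixing parameter alpha in [0, 1], strength lambda), then the ensemble
prediction for a sample is the arithmetic mean of the member models'
predicted probabilities — integration happens at the prediction level,
never by concatenating features.

The default family regresses a 0/1 response indicator under squared loss
(predictions clipped to [0, 1]); a penalized-logistic family is available.
Model performance (ROC / AUC) is always computed from out-of-fold CV
predictions averaged over repeats, not from in-sample refits, because
in-sample ROC of a tuned model is optimistically biased.

Standardization is internal: features are centered and unit-scaled using
training-fold statistics only, so shifting or rescaling raw inputs does
not change the selected panel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression, enet_path
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold

from .data import OmicsMatrix, ResponseSpec, Study
from .genesets import EnrichmentResult
from .pca import PCAResult, run_pca

__all__ = [
    "CVConfig",
    "HyperGrid",
    "PanelModel",
    "ROCCurve",
    "EnsembleResult",
    "elastic_net_path",
    "repeated_cv_tune",
    "ensemble",
    "roc_curve",
    "importance",
    "panel_intersections",
    "panel_projection",
    "panel_network",
]

#: alpha below this is treated as pure ridge when deriving the auto lambda grid
_ALPHA_FLOOR = 1e-3


@dataclass(frozen=True)
class CVConfig:
    folds: int = 5
    repeats: int = 5
    seed: int = 0
    metric: str = "auc"  # "auc" | "accuracy"
    family: str = "gaussian_on_indicator"  # | "binomial"

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")
        if self.metric not in ("auc", "accuracy"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.family not in ("gaussian_on_indicator", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class HyperGrid:
    """Elastic-net tuning grid; lambdas may be "auto" (log-spaced path)."""

    alphas: tuple[float, ...] = tuple(np.round(np.arange(0, 1.01, 0.1), 1))
    lambdas: tuple[float, ...] | str = "auto"
    n_auto_lambdas: int = 50
    lambda_min_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if not self.alphas or any(a < 0 or a > 1 for a in self.alphas):
            raise ValueError("alphas must be a non-empty list within [0, 1]")
        if isinstance(self.lambdas, tuple):
            if not self.lambdas or any(l <= 0 for l in self.lambdas):
                raise ValueError("explicit lambdas must be positive")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class PanelModel:
    """One dataset's tuned elastic-net classifier."""

    dataset_name: str
    alpha: float
    lam: float
    intercept: float
    coefficients: pd.Series  # standardized scale, index = feature ids
    selected_features: list[str]
    oof_scores: np.ndarray  # per sample, averaged over repeats
    cv_metric_table: pd.DataFrame  # alpha, lambda, mean_metric, sd_metric
    labels01: np.ndarray
    sample_index: np.ndarray  # positions within the parent Study
    cv_mean_metric: float


@dataclass
class EnsembleResult:
    members: list[PanelModel]
    ensemble_oof: np.ndarray
    rocs: dict[str, ROCCurve]  # member name -> curve, plus "ensemble"
    intersections: pd.DataFrame | None
    labels01: np.ndarray


# ---------------------------------------------------------------------------
# solvers


def _check_standardized(X: np.ndarray) -> None:
    live = X.std(axis=0) > 0
    if np.any(np.abs(X[:, live].mean(axis=0)) > 1e-6) or np.any(
        np.abs(X[:, live].std(axis=0) - 1) > 1e-4
    ):
        raise ValueError("X must be column-standardized (mean 0, sd 1)")


def _ridge_path(Xc: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Closed-form ridge for alpha=0: (X'X/n + lam I) b = X'y/n, via SVD."""
    n = len(yc)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    uty = U.T @ yc
    coefs = np.empty((Xc.shape[1], len(lambdas)))
    for i, lam in enumerate(lambdas):
        shrink = (s / n) / (s**2 / n + lam)
        coefs[:, i] = Vt.T @ (shrink * uty)
    return coefs


def elastic_net_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    tol: float = 1e-4,
) -> tuple[np.ndarray, float]:
    """Coefficients (p x len(lambdas)) of the elastic-net fit, plus intercept.

    Minimizes (1/2n)||y - b0 - Xb||^2 + lam * (alpha*||b||_1 +
    (1-alpha)/2 * ||b||_2^2) for each lam.  X must be standardized;
    zero-variance columns are excluded (coefficient 0).  With X centered
    the intercept is mean(y).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_standardized(X)
    lambdas = np.asarray(lambdas, dtype=float)
    order = np.argsort(lambdas)[::-1]  # descending for warm starts
    live = X.std(axis=0) > 0
    Xl = X[:, live]
    yc = y - y.mean()
    if alpha <= 0:
        coefs_live = _ridge_path(Xl, yc, lambdas[order])
    else:
        _, coefs_live, _ = enet_path(
            Xl, yc, l1_ratio=alpha, alphas=lambdas[order], max_iter=10_000, tol=tol
        )
    coefs = np.zeros((X.shape[1], len(lambdas)))
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    coefs[live] = coefs_live[:, inv]
    return coefs, float(y.mean())


def _binomial_path(
    X: np.ndarray, y01: np.ndarray, alpha: float, lambdas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Penalized logistic fits (saga) matching the per-sample lambda scale."""
    n = len(y01)
    coefs = np.empty((X.shape[1], len(lambdas)))
    intercepts = np.empty(len(lambdas))
    live = X.std(axis=0) > 0
    for i, lam in enumerate(lambdas):
        clf = LogisticRegression(
            penalty="elasticnet",
            solver="saga",
            l1_ratio=alpha,
            C=1.0 / (n * lam),
            max_iter=5000,
            tol=1e-6,
        )
        clf.fit(X[:, live], y01)
        coefs[:, i] = 0.0
        coefs[live, i] = clf.coef_[0]
        intercepts[i] = clf.intercept_[0]
    return coefs, intercepts


def _standardize(train: np.ndarray, apply_to: np.ndarray) -> np.ndarray:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    out = (apply_to - mu) / sd_safe
    out[:, sd == 0] = 0.0
    return out


def _auto_lambdas(
    Xs: np.ndarray, y: np.ndarray, alpha: float, grid: HyperGrid
) -> np.ndarray:
    """glmnet-style path: lambda_max down to lambda_min_ratio * lambda_max."""
    n = len(y)
    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean())))) / (
        n * max(alpha, _ALPHA_FLOOR)
    )
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, grid.lambda_min_ratio * lam_max, grid.n_auto_lambdas)


def _metric_matrix(
    preds: np.ndarray, y: np.ndarray, metric: str
) -> np.ndarray:
    """Metric per grid column for a (n_test x G) prediction matrix."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    if metric == "auc":
        if n1 == 0 or n0 == 0:
            return np.full(preds.shape[1], np.nan)
        r = rankdata(preds, axis=0)
        return (r[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)
    return ((preds > 0.5) == y[:, None]).mean(axis=0)


def dichotomize(
    response: ResponseSpec, labels: np.ndarray, level: str | None = None
) -> tuple[np.ndarray, np.ndarray, str]:
    """0/1 coding of (chosen level) vs (reference); other samples dropped."""
    labels = np.asarray(labels).astype(str)
    level = level or response.non_reference_levels[0]
    if level not in response.levels or level == response.reference_level:
        raise ValueError(f"invalid comparison level {level!r}")
    keep = np.flatnonzero(
        (labels == level) | (labels == response.reference_level)
    )
    y = (labels[keep] == level).astype(float)
    return keep, y, level


def repeated_cv_tune(
    dataset: OmicsMatrix,
    response: ResponseSpec,
    labels: np.ndarray,
    grid: HyperGrid | None = None,
    cv: CVConfig | None = None,
    level: str | None = None,
) -> PanelModel:
    """Tune (alpha, lambda) by repeated stratified CV; refit on all samples.

    Folds are drawn deterministically from the seed.  Standardization is
    fit on training folds only.  The winning grid point maximizes the
    mean metric over folds x repeats, with ties broken toward the largest
    lambda (sparsest model) then the largest alpha.  Out-of-fold scores
    at the winner are averaged over repeats and retained.
    """
    grid = grid or HyperGrid()
    cv = cv or CVConfig()
    keep, y, level = dichotomize(response, labels, level)
    X = dataset.values[keep]
    n = len(y)
    class_counts = [int((y == 0).sum()), int((y == 1).sum())]
    if cv.folds > min(class_counts):
        raise ValueError(
            f"folds={cv.folds} exceeds the smallest class count {min(class_counts)}"
        )

    # shared lambda grid per alpha, anchored on the full standardized data
    Xs_full = _standardize(X, X)
    lambdas_per_alpha: dict[float, np.ndarray] = {}
    for a in grid.alphas:
        if isinstance(grid.lambdas, str):
            lambdas_per_alpha[a] = _auto_lambdas(Xs_full, y, a, grid)
        else:
            lambdas_per_alpha[a] = np.asarray(grid.lambdas, dtype=float)

    splitter = RepeatedStratifiedKFold(
        n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed
    )
    n_lam = len(next(iter(lambdas_per_alpha.values())))
    n_grid = len(grid.alphas) * n_lam
    metric_sum = np.zeros(n_grid)
    metric_sumsq = np.zeros(n_grid)
    n_splits_done = 0
    oof_sum = np.zeros((n, n_grid))
    oof_cnt = np.zeros(n)

    for train_idx, test_idx in splitter.split(X, y):
        Xtr = X[train_idx]
        Xs_tr = _standardize(Xtr, Xtr)
        Xs_te = _standardize(Xtr, X[test_idx])
        ytr = y[train_idx]
        preds = np.empty((len(test_idx), n_grid))
        col = 0
        for a in grid.alphas:
            lams = lambdas_per_alpha[a]
            if cv.family == "binomial":
                coefs, b0s = _binomial_path(Xs_tr, ytr, a, lams)
                eta = Xs_te @ coefs + b0s
                block = 1.0 / (1.0 + np.exp(-eta))
            else:
                coefs, b0 = elastic_net_path(Xs_tr, ytr, a, lams)
                block = np.clip(Xs_te @ coefs + b0, 0.0, 1.0)
            preds[:, col : col + len(lams)] = block
            col += len(lams)
        m = _metric_matrix(preds, y[test_idx], cv.metric)
        metric_sum += m
        metric_sumsq += m**2
        n_splits_done += 1
        oof_sum[test_idx] += preds
        oof_cnt[test_idx] += 1

    mean_metric = metric_sum / n_splits_done
    sd_metric = np.sqrt(
        np.maximum(metric_sumsq / n_splits_done - mean_metric**2, 0.0)
    )

    # grid bookkeeping + winner with deterministic tie-breaks
    grid_alpha = np.repeat(list(grid.alphas), n_lam)
    grid_lambda = np.concatenate([lambdas_per_alpha[a] for a in grid.alphas])
    best = np.flatnonzero(mean_metric == np.nanmax(mean_metric))
    best = best[np.lexsort((-grid_alpha[best], -grid_lambda[best]))][0]
    alpha_star = float(grid_alpha[best])
    lam_star = float(grid_lambda[best])

    oof = oof_sum[:, best] / oof_cnt  # averaged over repeats

    # final refit on all samples at the winner
    if cv.family == "binomial":
        coefs, b0s = _binomial_path(Xs_full, y, alpha_star, np.array([lam_star]))
        coef_star, b0_star = coefs[:, 0], float(b0s[0])
    else:
        coefs, b0_star = elastic_net_path(
            Xs_full, y, alpha_star, np.array([lam_star])
        )
        coef_star = coefs[:, 0]

    coef_series = pd.Series(coef_star, index=dataset.feature_ids)
    selected = coef_series.index[coef_series != 0].tolist()
    table = pd.DataFrame(
        {
            "alpha": grid_alpha,
            "lambda": grid_lambda,
            "mean_metric": mean_metric,
            "sd_metric": sd_metric,
        }
    )
    return PanelModel(
        dataset_name=dataset.name,
        alpha=alpha_star,
        lam=lam_star,
        intercept=b0_star,
        coefficients=coef_series,
        selected_features=selected,
        oof_scores=oof,
        cv_metric_table=table,
        labels01=y,
        sample_index=keep,
        cv_mean_metric=float(mean_metric[best]),
    )


# ---------------------------------------------------------------------------
# ensembling & evaluation


def roc_curve(scores: np.ndarray, labels01: np.ndarray) -> ROCCurve:
    """ROC points (ties grouped into one step) and trapezoidal AUC."""
    labels01 = np.asarray(labels01, dtype=float)
    if len(np.unique(labels01)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels01, scores, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def ensemble(models: list[PanelModel]) -> EnsembleResult:
    """Average member out-of-fold probabilities; ROC per member + ensemble."""
    if not models:
        raise ValueError("need at least one member model")
    ref = models[0]
    for m in models[1:]:
        if not np.array_equal(m.labels01, ref.labels01) or not np.array_equal(
            m.sample_index, ref.sample_index
        ):
            raise ValueError(
                f"member {m.dataset_name!r} has mismatched samples or labels"
            )
    oof = np.mean([m.oof_scores for m in models], axis=0)
    rocs = {m.dataset_name: roc_curve(m.oof_scores, m.labels01) for m in models}
    rocs["ensemble"] = roc_curve(oof, ref.labels01)
    inter = panel_intersections(models) if len(models) >= 2 else None
    return EnsembleResult(
        members=models,
        ensemble_oof=oof,
        rocs=rocs,
        intersections=inter,
        labels01=ref.labels01,
    )


def importance(model: PanelModel) -> pd.DataFrame:
    """Selected biomarkers ranked by |standardized coefficient|, sign kept."""
    coefs = model.coefficients[model.coefficients != 0]
    frame = pd.DataFrame(
        {"feature": coefs.index, "coefficient": coefs.to_numpy()}
    )
    frame["abs_coef"] = frame["coefficient"].abs()
    frame = frame.sort_values(
        ["abs_coef", "feature"], ascending=[False, True], kind="mergesort"
    ).drop(columns="abs_coef")
    return frame.reset_index(drop=True)


def panel_intersections(models: list[PanelModel]) -> pd.DataFrame:
    """UpSet-style exact-subset counts of panel membership by feature name."""
    if len(models) < 2:
        raise ValueError("need >= 2 panels")
    names = [m.dataset_name for m in models]
    membership: dict[str, frozenset[str]] = {}
    for m in models:
        for f in m.selected_features:
            membership[f] = membership.get(f, frozenset()) | {m.dataset_name}
    rows = []
    for r in range(1, len(names) + 1):
        for subset in itertools.combinations(names, r):
            sub = frozenset(subset)
            count = sum(1 for mem in membership.values() if mem == sub)
            rows.append({"panels": "+".join(subset), "degree": r, "count": count})
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["count", "panels"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def panel_projection(
    study: Study, features: dict[str, list[str]], k: int = 5
) -> tuple[dict[str, PCAResult], pd.DataFrame]:
    """PCA of each dataset restricted to its panel, plus a clustered heatmap.

    The heatmap matrix concatenates the standardized panel columns of all
    datasets; rows (samples) and columns (features) are ordered by
    average-linkage hierarchical clustering on Euclidean distance.
    """
    pcas: dict[str, PCAResult] = {}
    blocks = []
    for ds_name, feats in features.items():
        if not feats:
            continue
        ds = study.dataset(ds_name)
        missing = [f for f in feats if f not in ds.frame.columns]
        if missing:
            raise ValueError(f"features {missing} absent from dataset {ds_name!r}")
        sub = ds.frame[feats]
        sub_matrix = OmicsMatrix(ds_name, sub, ds.is_count)
        kk = min(k, sub.shape[1], study.n - 1)
        pcas[ds_name] = run_pca(sub_matrix, k=kk, scale=False)
        Z = sub.to_numpy(dtype=float)
        sd = Z.std(axis=0, ddof=1)
        Z = (Z - Z.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        blocks.append(pd.DataFrame(Z, columns=[f"{ds_name}:{f}" for f in feats]))
    if not blocks:
        raise ValueError("no panel features to project")
    hm = pd.concat(blocks, axis=1)

    def _cluster_order(M: np.ndarray) -> np.ndarray:
        if M.shape[0] < 3:
            return np.arange(M.shape[0])
        link = hierarchy.linkage(M, method="average", metric="euclidean")
        return hierarchy.leaves_list(link)

    row_order = _cluster_order(hm.to_numpy())
    col_order = _cluster_order(hm.to_numpy().T)
    hm = hm.iloc[row_order, col_order]
    return pcas, hm


def panel_network(
    study: Study,
    panel_features: dict[str, list[str]],
    enrichment: EnrichmentResult | None,
    fdr: float = 0.05,
    r_cutoff: float = 0.75,
) -> pd.DataFrame:
    """Edge list linking biomarkers to pathways and to correlated biomarkers.

    Biomarker-pathway edges connect each significantly enriched set
    (adj_p < fdr) to the panel biomarkers in its overlap; biomarker-
    biomarker edges connect pairs with |Pearson r| >= r_cutoff across all
    samples (cross-dataset pairs allowed since samples align).
    """
    if not (0 < r_cutoff <= 1) or not (0 < fdr < 1):
        raise ValueError("need 0 < r_cutoff <= 1 and 0 < fdr < 1")
    cols: dict[str, np.ndarray] = {}
    for ds_name, feats in panel_features.items():
        ds = study.dataset(ds_name)
        for f in feats:
            if f not in ds.frame.columns:
                raise ValueError(f"feature {f!r} absent from dataset {ds_name!r}")
            cols[f"{ds_name}:{f}"] = ds.frame[f].to_numpy(dtype=float)
    edges = []
    names = sorted(cols)
    live = [nm for nm in names if np.ptp(cols[nm]) > 0]
    for a, b in itertools.combinations(live, 2):
        r = float(np.corrcoef(cols[a], cols[b])[0, 1])
        if abs(r) >= r_cutoff:
            edges.append(
                {"source": a, "target": b, "edge_type": "correlation", "weight": r}
            )
    if enrichment is not None and len(enrichment.table):
        sig = enrichment.significant_sets(fdr)
        bare = {nm.split(":", 1)[1].upper(): nm for nm in names}
        for _, row in sig.iterrows():
            for gene in str(row["genes"]).split(";"):
                if gene in bare:
                    edges.append(
                        {
                            "source": bare[gene],
                            "target": row["set"],
                            "edge_type": "pathway",
                            "weight": float(-np.log10(max(row["adj_p"], 1e-300))),
                        }
                    )
    return pd.DataFrame(edges, columns=["source", "target", "edge_type", "weight"])
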