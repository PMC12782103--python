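"""Per-dataset PCA and metadata association of principal-component scores.

Each omics dataset is decomposed by SVD after column centering (optional
unit-variance scaling).  Up to five components are retained.  Sources of
variation are attributed by regressing each PC score onto each metadata
variable and collecting the overall ANOVA F-test p-values into a
variables x components association matrix, optionally BH-adjusted across
the whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import MetadataTable, OmicsMatrix, ResponseSpec

__all__ = [
    "PCAResult",
    "AssociationMatrix",
    "run_pca",
    "pc_metadata_association",
    "score_plot_data",
]

MAX_COMPONENTS = 5


@dataclass
class PCAResult:
    dataset_name: str
    k: int
    scores: pd.DataFrame  # n x k, columns PC1..PCk
    loadings: pd.DataFrame  # p x k, index = feature ids
    var_explained: np.ndarray  # k proportions, non-increasing
    var_explained_full: np.ndarray  # all min(n-1, p) proportions, sums to 1


@dataclass
class AssociationMatrix:
    raw_p: pd.DataFrame  # variables x PCs
    adj_p: pd.DataFrame | None  # BH across the whole grid, if requested
    method: str = "anova_f"


def run_pca(dataset: OmicsMatrix, k: int = MAX_COMPONENTS, scale: bool = False) -> PCAResult:
    """Centered (optionally unit-scaled) PCA via singular value decomposition.

    ``var_explained_i = sigma_i^2 / sum(sigma^2)`` over the full
    decomposition.  Sign convention: each loading column is flipped so its
    largest-magnitude entry is positive, making outputs reproducible
    across platforms.
    """
    X = dataset.values
    n, p = X.shape
    k = min(k, MAX_COMPONENTS)
    if k < 1 or k > min(n - 1, p):
        raise ValueError(f"k={k} must be in [1, min(n-1, p)={min(n - 1, p)}]")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        const = np.flatnonzero(sd == 0)
        if const.size:
            raise ValueError(
                f"constant column(s) {[dataset.feature_ids[i] for i in const[:5]]} "
                "cannot be unit-scaled"
            )
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    full_ratio = s**2 / total
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * s[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        dataset_name=dataset.name,
        k=k,
        scores=pd.DataFrame(scores, columns=cols),
        loadings=pd.DataFrame(Vt[:k].T, index=dataset.feature_ids, columns=cols),
        var_explained=full_ratio[:k],
        var_explained_full=full_ratio,
    )


def _regression_f_pvalue(y: np.ndarray, design: np.ndarray) -> float:
    """Overall F-test p of OLS y ~ [1, design] against the intercept-only model."""
    n = len(y)
    X = np.column_stack([np.ones(n), design])
    q = X.shape[1] - 1
    df2 = n - X.shape[1]
    if df2 <= 0:
        return float("nan")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return float("nan")
    if rss <= 0:
        return 0.0
    f_stat = ((tss - rss) / q) / (rss / df2)
    return float(stats.f.sf(f_stat, q, df2))


def _variable_design(values: pd.Series, kind: str) -> np.ndarray | None:
    """Indicator coding for categoricals, centered column for numericals.

    Returns None for zero-variance variables (association not applicable).
    """
    if kind == "categorical":
        levels = pd.unique(values.astype(str))
        if len(levels) < 2:
            return None
        return np.column_stack(
            [(values.astype(str) == lev).to_numpy(float) for lev in levels[1:]]
        )
    x = values.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        return None
    return x.reshape(-1, 1)


def pc_metadata_association(
    pca: PCAResult, metadata: MetadataTable, apply_fdr: bool = False
) -> AssociationMatrix:
    """ANOVA F-test p-value for every (metadata variable, PC score) pair.

    One p per cell regardless of how many levels the variable has.  When
    ``apply_fdr`` is set, BH is applied jointly across the whole grid.
    Zero-variance variables yield NaN cells (not applicable).
    """
    if metadata.n != len(pca.scores):
        raise ValueError("metadata and PC scores are not aligned")
    variables = metadata.variables()
    raw = pd.DataFrame(
        np.nan, index=variables, columns=list(pca.scores.columns), dtype=float
    )
    for var in variables:
        design = _variable_design(metadata.frame[var], metadata.var_kind[var])
        if design is None:
            continue
        for pc in pca.scores.columns:
            raw.loc[var, pc] = _regression_f_pvalue(
                pca.scores[pc].to_numpy(), design
            )
    adj = None
    if apply_fdr:
        from .diffexp import benjamini_hochberg

        flat = raw.to_numpy().ravel()
        mask = ~np.isnan(flat)
        adj_flat = np.full_like(flat, np.nan)
        if mask.any():
            adj_flat[mask] = benjamini_hochberg(flat[mask])
        adj = pd.DataFrame(
            adj_flat.reshape(raw.shape), index=raw.index, columns=raw.columns
        )
    return AssociationMatrix(raw_p=raw, adj_p=adj)


def score_plot_data(
    pca: PCAResult, response: ResponseSpec, metadata: MetadataTable
) -> pd.DataFrame:
    """Long-format scatter-matrix table: one row per sample per PC pair."""
    labels = metadata.frame[response.name].astype(str).to_numpy()
    rows = []
    cols = list(pca.scores.columns)
    for a in range(pca.k):
        for b in range(a + 1, pca.k):
            for i in range(len(pca.scores)):
                rows.append(
                    {
                        "sample": i,
                        "pc_x": cols[a],
                        "pc_y": cols[b],
                        "score_x": float(pca.scores.iloc[i, a]),
                        "score_y": float(pca.scores.iloc[i, b]),
                        "response": labels[i],
                    }
                )
    return pd.DataFrame(
        rows, columns=["sample", "pc_x", "pc_y", "score_x", "score_y", "response"]
    )
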