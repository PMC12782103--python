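"""Static figure rendering for the pipeline stages (matplotlib, Agg)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_volcano",
    "plot_pca_scatter",
    "plot_association_heatmap",
    "plot_roc",
    "plot_enrichment_dotplot",
    "plot_network",
]

_SAVEKW = dict(dpi=110, bbox_inches="tight", metadata={"Software": None})


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, **_SAVEKW)
    plt.close(fig)
    return path


def plot_volcano(volcano: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = volcano["significant"].to_numpy(bool)
    ax.scatter(volcano["log2fc"][~sig], volcano["neg_log10_p"][~sig], s=6, c="grey")
    ax.scatter(volcano["log2fc"][sig], volcano["neg_log10_p"][sig], s=8, c="crimson")
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("-log10 p")
    ax.set_title(title)
    return _save(fig, path)


def plot_pca_scatter(score_data: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    panels = score_data[["pc_x", "pc_y"]].drop_duplicates().to_numpy()
    ncol = max(1, int(np.ceil(np.sqrt(len(panels)))))
    nrow = int(np.ceil(len(panels) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3 * nrow), squeeze=False)
    levels = list(dict.fromkeys(score_data["response"]))
    for idx, (px, py) in enumerate(panels):
        ax = axes[idx // ncol][idx % ncol]
        sub = score_data[(score_data["pc_x"] == px) & (score_data["pc_y"] == py)]
        for lev in levels:
            ss = sub[sub["response"] == lev]
            ax.scatter(ss["score_x"], ss["score_y"], s=8, label=str(lev))
        ax.set_xlabel(px)
        ax.set_ylabel(py)
    for idx in range(len(panels), nrow * ncol):
        axes[idx // ncol][idx % ncol].axis("off")
    axes[0][0].legend(fontsize=7)
    fig.suptitle(title)
    return _save(fig, path)


def plot_association_heatmap(raw_p: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    with np.errstate(divide="ignore"):
        mat = -np.log10(raw_p.to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(1.2 * raw_p.shape[1] + 2, 0.5 * raw_p.shape[0] + 2))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_xticks(range(raw_p.shape[1]), raw_p.columns)
    ax.set_yticks(range(raw_p.shape[0]), raw_p.index)
    fig.colorbar(im, ax=ax, label="-log10 p")
    ax.set_title(title)
    return _save(fig, path)


def plot_roc(rocs: dict, path: str | Path, title: str = "ROC") -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, curve in rocs.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC={curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    ax.set_title(title)
    return _save(fig, path)


def plot_enrichment_dotplot(table: pd.DataFrame, path: str | Path, top: int = 20) -> Path:
    sub = table.nsmallest(top, "adj_p")
    fig, ax = plt.subplots(figsize=(6, 0.3 * max(len(sub), 4) + 1.5))
    sc = ax.scatter(
        sub["gene_ratio"],
        range(len(sub)),
        s=12 * sub["k"] + 10,
        c=-np.log10(np.maximum(sub["adj_p"], 1e-300)),
        cmap="plasma",
    )
    ax.set_yticks(range(len(sub)), sub["set"])
    ax.invert_yaxis()
    ax.set_xlabel("gene ratio (k / query)")
    fig.colorbar(sc, ax=ax, label="-log10 adj p")
    return _save(fig, path)


def plot_network(edges: pd.DataFrame, path: str | Path) -> Path:
    import networkx as nx

    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_edge(e["source"], e["target"], kind=e["edge_type"])
    fig, ax = plt.subplots(figsize=(6, 6))
    if g.number_of_nodes():
        pos = nx.spring_layout(g, seed=0)
        colors = [
            "tab:orange" if d["kind"] == "pathway" else "tab:blue"
            for *_, d in g.edges(data=True)
        ]
        nx.draw_networkx(g, pos, ax=ax, node_size=80, font_size=6, edge_color=colors)
    ax.axis("off")
    return _save(fig, path)
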