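"""Over-representation analysis against GMT collections, and drug-reversal scoring.

ORA uses the hypergeometric upper tail with the *tested-feature universe*:
the background is the set of features actually tested in the differential
expression step, which corrects the sampling bias of querying only
significant genes.  Drug-reversal scoring runs ORA of the up-regulated
query genes against each perturbation's *down* set and vice versa, then
combines the two directions into a single ranking score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import benjamini_hochberg

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "ora",
    "drug_reversal",
    "looks_like_gene_symbols",
]

#: uppercase alphanumeric symbol, starts with a letter, length 1-10
SYMBOL_RE = re.compile(r"^[A-Z][A-Z0-9]{0,9}$")


class GMTError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets (upper-cased symbols, deduplicated within a set)."""

    name: str
    sets: dict[str, list[str]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def vocabulary(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out


@dataclass
class EnrichmentResult:
    """Per-set overlap statistics and hypergeometric p-values."""

    table: pd.DataFrame  # set, k, K, n_query, N, gene_ratio, p, adj_p, genes
    n_dropped_sets: int  # sets empty after universe intersection
    n_dropped_query: int  # query genes outside the universe

    def significant_sets(self, fdr: float) -> pd.DataFrame:
        return self.table[self.table["adj_p"] < fdr]


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: tab-delimited name, description, members...

    Symbols are upper-cased; duplicates within a set are counted once.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GMTError(
                f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
            )
        set_name = fields[0]
        if set_name in sets:
            raise GMTError(f"{path}:{lineno}: duplicate set name {set_name!r}")
        members = list(dict.fromkeys(g.strip().upper() for g in fields[2:] if g.strip()))
        sets[set_name] = members
    return GeneSetCollection(name=name or path.stem, sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([set_name, collection.source or "na", *members])
        for set_name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def looks_like_gene_symbols(feature_ids: list[str], threshold: float = 0.5) -> bool:
    """Heuristic human-symbol detection enabling enrichment for a dataset."""
    if not feature_ids:
        return False
    hits = sum(bool(SYMBOL_RE.match(f.upper())) for f in feature_ids)
    return hits / len(feature_ids) >= threshold


def ora(
    query: list[str],
    universe: list[str],
    collection: GeneSetCollection,
) -> EnrichmentResult:
    """Hypergeometric over-representation of the query within each set.

    For each set: K = |set ∩ universe|, k = |set ∩ query|, and
    p = P(X >= k) for X hypergeometric(N=|universe|, K, n_query).
    Sets empty after universe intersection are dropped (counted); BH is
    applied across the tested sets.
    """
    uni = list(dict.fromkeys(g.upper() for g in universe))
    if len(uni) < 2:
        raise ValueError("universe must contain >= 2 genes")
    uni_set = set(uni)
    q = list(dict.fromkeys(g.upper() for g in query))
    dropped_query = len(q) - sum(g in uni_set for g in q)
    q = [g for g in q if g in uni_set]
    if not q:
        raise ValueError("query is empty after intersecting with the universe")
    q_set = set(q)
    N, n_q = len(uni), len(q)

    rows = []
    dropped_sets = 0
    for set_name, members in collection.sets.items():
        inter = [g for g in members if g in uni_set]
        K = len(inter)
        if K == 0:
            dropped_sets += 1
            continue
        overlap = [g for g in inter if g in q_set]
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_q))
        rows.append(
            {
                "set": set_name,
                "k": k,
                "K": K,
                "n_query": n_q,
                "N": N,
                "gene_ratio": k / n_q,
                "p": min(p, 1.0),
                "genes": ";".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "k", "K", "n_query", "N", "gene_ratio", "p", "genes"]
    )
    if len(table):
        table["adj_p"] = benjamini_hochberg(table["p"].to_numpy())
    else:
        table["adj_p"] = pd.Series(dtype=float)
    table = table[
        ["set", "k", "K", "n_query", "N", "gene_ratio", "p", "adj_p", "genes"]
    ].sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(
        table=table, n_dropped_sets=dropped_sets, n_dropped_query=dropped_query
    )


def drug_reversal(
    up_genes: list[str],
    down_genes: list[str],
    pert_up: GeneSetCollection,
    pert_down: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Rank perturbations that reverse the query signature.

    Up-regulated query genes are tested against each perturbation's
    *down* set, and down-regulated query genes against the *up* set
    (outer join on perturbation names; a missing side contributes p = 1).
    combined_score = -log10(adj_p_up_vs_down) - log10(adj_p_down_vs_up),
    sorted descending with a deterministic tie-break on the name.
    """
    if not up_genes and not down_genes:
        raise ValueError("both query gene lists are empty")

    def _component(query: list[str], coll: GeneSetCollection) -> dict[str, float]:
        if not query:
            return {}
        try:
            res = ora(query, universe, coll)
        except ValueError:
            return {}
        return dict(zip(res.table["set"], res.table["adj_p"]))

    p_uvd = _component(up_genes, pert_down)
    p_dvu = _component(down_genes, pert_up)
    names = sorted(set(pert_up.sets) | set(pert_down.sets))
    rows = []
    for name in names:
        a = p_uvd.get(name, 1.0)
        b = p_dvu.get(name, 1.0)
        score = -np.log10(max(a, 1e-300)) + -np.log10(max(b, 1e-300))
        rows.append(
            {
                "perturbation": name,
                "p_up_vs_down": a,
                "p_down_vs_up": b,
                "combined_score": float(score),
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["combined_score", "perturbation"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
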