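"""Synthetic multimodal studies with known ground truth.

Every stage of the pipeline is testable without downloads: the generator
emits an aligned Study (metadata + J omics matrices + response) whose
planted structure — group-shifted features, batch shifts, count
log-fold-changes — is recorded in a GroundTruth object.

Gaussian mode draws null features iid N(0, 1) and shifts planted
features by ±delta/2 per group (delta in units of the feature standard
deviation).  Negative-binomial mode draws gamma-Poisson counts with a
group log2-fold-change of delta on planted features, for exercising the
count/precision-weight path.  Effects are mean shifts with no feature
correlation by default; an optional equicorrelation within blocks of 10
stresses penalized-model feature grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MetadataTable, OmicsMatrix, ResponseSpec, Study, classify_variables
from .genesets import GeneSetCollection

__all__ = [
    "SimSpec",
    "GroundTruth",
    "simulate_study",
    "simulate_reversal_fixture",
]


@dataclass(frozen=True)
class SimSpec:
    """Conditions of a simulated study.

    delta is the planted effect: a mean shift in sd units (gaussian) or a
    log2 fold-change (negative_binomial).  A nonzero batch_shift adds a
    constant (in sd units) to every feature of batch-1 samples, planting
    a dominant axis of variation attributable to batch.
    """

    n: int = 100
    group_proportions: tuple[float, ...] = (0.5, 0.5)
    group_names: tuple[str, ...] = ("control", "case")
    p: tuple[int, ...] = (200, 200)
    q: tuple[int, ...] = (10, 10)
    delta: float = 1.0
    noise: str = "gaussian"  # | "negative_binomial"
    nb_dispersion: float = 0.2
    nb_base_log_mean: float = 5.0  # natural-log mean count scale
    batch_shift: float = 0.0
    block_correlation: float = 0.0  # equicorrelation within blocks of 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if len(self.group_proportions) != len(self.group_names):
            raise ValueError("one proportion per group name")
        if len(self.p) != len(self.q):
            raise ValueError("p and q must have one entry per dataset")
        if any(qj > pj for pj, qj in zip(self.p, self.q)):
            raise ValueError("planted q_j must not exceed p_j")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.noise not in ("gaussian", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class GroundTruth:
    planted: dict[str, list[str]]  # dataset name -> planted feature names
    group_labels: np.ndarray
    batch_labels: np.ndarray


def _feature_names(dataset_idx: int, p: int) -> list[str]:
    # uppercase-symbol-like ids so enrichment detection treats them as genes
    return [f"D{dataset_idx + 1}G{i + 1}" for i in range(p)]


def _group_assignment(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    counts = np.floor(np.asarray(spec.group_proportions) * spec.n).astype(int)
    while counts.sum() < spec.n:
        counts[int(np.argmax(np.asarray(spec.group_proportions)))] += 1
    labels = np.repeat(spec.group_names, counts)
    rng.shuffle(labels)
    return labels


def _gaussian_block(
    spec: SimSpec, rng: np.random.Generator, n: int, p: int
) -> np.ndarray:
    X = rng.standard_normal((n, p))
    rho = spec.block_correlation
    if rho > 0:
        for start in range(0, p, 10):
            width = min(10, p - start)
            shared = rng.standard_normal(n)[:, None]
            X[:, start : start + width] = (
                np.sqrt(rho) * shared
                + np.sqrt(1 - rho) * X[:, start : start + width]
            )
    return X


def simulate_study(spec: SimSpec) -> tuple[Study, GroundTruth]:
    """Generate an aligned Study plus its ground truth; seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    groups = _group_assignment(spec, rng)
    signed = np.where(groups == spec.group_names[0], -0.5, 0.5)
    batch = rng.integers(0, 2, size=spec.n)

    datasets: list[OmicsMatrix] = []
    planted: dict[str, list[str]] = {}
    for j, (pj, qj) in enumerate(zip(spec.p, spec.q)):
        name = f"omics{j + 1}"
        feats = _feature_names(j, pj)
        planted_idx = np.arange(qj)
        if spec.noise == "gaussian":
            X = _gaussian_block(spec, rng, spec.n, pj)
            X[:, planted_idx] += spec.delta * signed[:, None]
            if spec.batch_shift != 0.0:
                X += spec.batch_shift * batch[:, None]
            frame = pd.DataFrame(X, columns=feats)
            datasets.append(OmicsMatrix(name, frame, is_count=False))
        else:
            log_mu = rng.normal(spec.nb_base_log_mean, 1.0, size=pj)
            mu = np.exp(log_mu)[None, :] * np.ones((spec.n, 1))
            lfc = np.zeros(pj)
            lfc[planted_idx] = spec.delta
            mu = mu * 2.0 ** (lfc[None, :] * signed[:, None])
            shape = 1.0 / spec.nb_dispersion
            lam = rng.gamma(shape, mu / shape)
            counts = rng.poisson(lam).astype(float)
            frame = pd.DataFrame(counts, columns=feats)
            datasets.append(OmicsMatrix(name, frame, is_count=True))
        planted[name] = [feats[i] for i in planted_idx]

    meta = pd.DataFrame(
        {
            "group": groups.astype(str),
            "batch": batch.astype(str),
            "age": np.round(rng.normal(50, 10, size=spec.n), 1),
            "sex": rng.choice(["F", "M"], size=spec.n),
        }
    )
    var_kind = classify_variables(meta.astype(str))
    var_kind["group"] = "categorical"
    meta_typed = meta.copy()
    for col, kind in var_kind.items():
        meta_typed[col] = (
            pd.to_numeric(meta[col]) if kind == "numerical" else meta[col].astype(str)
        )
    metadata = MetadataTable(meta_typed, var_kind)
    response = ResponseSpec("group", spec.group_names[0], tuple(spec.group_names))
    study = Study(metadata, datasets, response)
    truth = GroundTruth(planted=planted, group_labels=groups, batch_labels=batch)
    return study, truth


def simulate_complementary_study(
    n: int = 100,
    p: int = 100,
    q: int = 10,
    delta: float = 2.0,
    seed: int = 0,
) -> tuple[Study, GroundTruth]:
    """Two modalities each predictive of a different half of the cases.

    Cases are split into two halves; modality 1's planted features are
    shifted only in the first half and modality 2's only in the second,
    so each single-modality model can separate at most half of the cases
    and prediction-level averaging should beat either member.
    """
    rng = np.random.default_rng(seed)
    groups = np.array(["control"] * (n // 2) + ["case"] * (n - n // 2))
    rng.shuffle(groups)
    case_idx = np.flatnonzero(groups == "case")
    half1 = case_idx[: len(case_idx) // 2]
    half2 = case_idx[len(case_idx) // 2 :]

    datasets = []
    planted: dict[str, list[str]] = {}
    for j, half in enumerate((half1, half2)):
        feats = _feature_names(j, p)
        X = rng.standard_normal((n, p))
        X[np.ix_(half, np.arange(q))] += delta
        datasets.append(
            OmicsMatrix(f"omics{j + 1}", pd.DataFrame(X, columns=feats), is_count=False)
        )
        planted[f"omics{j + 1}"] = feats[:q]

    meta = pd.DataFrame({"group": groups.astype(str)})
    metadata = MetadataTable(meta, {"group": "categorical"})
    response = ResponseSpec("group", "control", ("control", "case"))
    study = Study(metadata, datasets, response)
    truth = GroundTruth(
        planted=planted, group_labels=groups, batch_labels=np.zeros(n, dtype=int)
    )
    return study, truth


def simulate_reversal_fixture(
    n_sets: int = 50,
    seed: int = 0,
    universe_size: int = 400,
    set_size: int = 50,
    query_size: int = 40,
    planted_overlap: int = 30,
    plant_signal: bool = True,
) -> tuple[list[str], list[str], GeneSetCollection, GeneSetCollection, list[str]]:
    """Perturbation collections with one planted reversal signature.

    The planted perturbation's *down* set is enriched for the query's
    up-regulated genes (and its up set for the query's down genes); all
    other sets are uniform draws from the universe.  With
    ``plant_signal=False`` every set is a uniform draw (null fixture).
    """
    if n_sets < 2:
        raise ValueError("need >= 2 perturbation sets")
    rng = np.random.default_rng(seed)
    universe = [f"G{i + 1}" for i in range(universe_size)]
    shuffled = list(universe)
    rng.shuffle(shuffled)
    up_genes = shuffled[:query_size]
    down_genes = shuffled[query_size : 2 * query_size]

    def _random_set() -> list[str]:
        return sorted(rng.choice(universe, size=set_size, replace=False).tolist())

    pert_up: dict[str, list[str]] = {}
    pert_down: dict[str, list[str]] = {}
    for i in range(n_sets):
        nm = f"PERT_{i + 1:03d}"
        pert_up[nm] = _random_set()
        pert_down[nm] = _random_set()
    if plant_signal:
        target = "PERT_001"
        rest = [g for g in universe if g not in up_genes]
        pert_down[target] = sorted(
            up_genes[:planted_overlap]
            + rng.choice(rest, size=set_size - planted_overlap, replace=False).tolist()
        )
        rest = [g for g in universe if g not in down_genes]
        pert_up[target] = sorted(
            down_genes[:planted_overlap]
            + rng.choice(rest, size=set_size - planted_overlap, replace=False).tolist()
        )
    up_coll = GeneSetCollection("pert_up", pert_up, source="synthetic")
    down_coll = GeneSetCollection("pert_down", pert_down, source="synthetic")
    return up_genes, down_genes, up_coll, down_coll, universe
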