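"""Similarity construction for both sides of the bipartite graph.

Two routes feed each similarity matrix: a curated source (functional
similarity table for the row entities, hierarchy-based semantic similarity
for the column entities) and a Gaussian interaction-profile kernel computed
from the association matrix, used wherever curation does not cover a pair.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import DataError, DegenerateProfileError
from .types import AssociationMatrix, DiseaseDAG, KernelBandwidth, SimilarityMatrix

__all__ = [
    "gaussian_bandwidth",
    "gaussian_profile_similarity",
    "fuse_mirna_similarity",
    "semantic_contribution_wang",
    "semantic_contribution_xuan",
    "semantic_similarity",
    "semantic_similarity_matrix",
    "fuse_disease_similarity",
]


def _profiles(Y: AssociationMatrix, axis: str) -> np.ndarray:
    if axis == "mirna":
        return Y.values
    if axis == "disease":
        return Y.values.T
    raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")


def gaussian_bandwidth(Y: AssociationMatrix, axis: str) -> KernelBandwidth:
    """Mean squared profile norm along the chosen axis.

    Raises
    ------
    DegenerateProfileError
        If the association matrix is all zero, which would give a zero
        bandwidth and an undefined kernel.
    """
    profiles = _profiles(Y, axis)
    theta = float((profiles**2).sum()) / profiles.shape[0]
    if theta <= 0.0:
        raise DegenerateProfileError(
            f"all-zero association profiles along axis {axis!r}: bandwidth is 0"
        )
    return KernelBandwidth(theta)


def gaussian_profile_similarity(Y: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Gaussian kernel of pairwise association-profile distances.

    Entry (i, j) is ``exp(-||p_i - p_j||^2 / theta)`` with the bandwidth from
    :func:`gaussian_bandwidth`.
    """
    theta = gaussian_bandwidth(Y, axis).value
    profiles = _profiles(Y, axis)
    sq_norms = (profiles**2).sum(axis=1)
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    values = np.exp(-d2 / theta)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    ids = Y.mirna_ids if axis == "mirna" else Y.disease_ids
    return SimilarityMatrix(values, list(ids))


def _fuse_curated(
    curated: SimilarityMatrix | None,
    fallback: SimilarityMatrix,
    what: str,
) -> SimilarityMatrix:
    """Take curated entries where both members are covered, else fallback."""
    ids = fallback.ids
    values = fallback.values.copy()
    mask = np.zeros_like(values, dtype=bool)
    if curated is not None:
        unknown = set(curated.ids) - set(ids)
        if unknown:
            raise DataError(
                f"curated {what} labels not present in association data: "
                f"{sorted(unknown)[:5]}"
            )
        pos = {name: k for k, name in enumerate(ids)}
        idx = np.array([pos[name] for name in curated.ids], dtype=int)
        values[np.ix_(idx, idx)] = curated.values
        mask[np.ix_(idx, idx)] = True
    # curated tables may carry rounding asymmetry; repair before validation
    values = 0.5 * (values + values.T)
    np.clip(values, 0.0, 1.0, out=values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(ids), curated_mask=mask & mask.T)


def fuse_mirna_similarity(
    MS: SimilarityMatrix | None, GMS: SimilarityMatrix
) -> SimilarityMatrix:
    """Functional similarity where both miRNAs are curated, Gaussian otherwise."""
    return _fuse_curated(MS, GMS, "miRNA similarity")


def semantic_contribution_wang(
    dag: DiseaseDAG, disease: str, delta: float = 0.5
) -> dict[str, float]:
    """Per-ancestor contribution decaying by ``delta`` per hierarchy level.

    The query disease contributes 1 to itself; each ancestor ``j`` contributes
    ``delta`` times the best contribution among its children inside the query
    disease's ancestor closure.
    """
    if not (0.0 < delta < 1.0):
        raise DataError(f"delta must lie in (0, 1), got {delta}")
    root = dag.resolve(disease)
    closure = dag.ancestor_closure(root)
    scores: dict[str, float] = {}

    def score(node: str) -> float:
        if node in scores:
            return scores[node]
        if node == root:
            value = 1.0
        else:
            value = max(
                delta * score(child)
                for child in dag.children_of(node)
                if child in closure
            )
        scores[node] = value
        return value

    for node in closure:
        score(node)
    return scores


def semantic_contribution_xuan(dag: DiseaseDAG, node: str) -> float:
    """Information content of a term: -log of its DAG-membership frequency."""
    term = dag.resolve(node)
    count = dag.membership_counts.get(term)
    if count is None:
        raise DataError(f"term {term!r} does not appear in any disease hierarchy")
    return -math.log(count / dag.total_diseases)


def semantic_similarity(
    dag: DiseaseDAG, i: str, j: str, model: str = "wang", delta: float = 0.5
) -> float:
    """Shared-ancestor similarity of two diseases under either contribution model."""
    ni = dag.ancestor_closure(i)
    nj = dag.ancestor_closure(j)
    shared = ni & nj
    if not shared:
        return 0.0
    if model == "wang":
        sci = semantic_contribution_wang(dag, i, delta)
        scj = semantic_contribution_wang(dag, j, delta)
    elif model == "xuan":
        sci = {t: semantic_contribution_xuan(dag, t) for t in ni}
        scj = {t: semantic_contribution_xuan(dag, t) for t in nj}
    else:
        raise ValueError(f"model must be 'wang' or 'xuan', got {model!r}")
    numerator = sum(sci[t] + scj[t] for t in shared)
    denominator = sum(sci.values()) + sum(scj.values())
    if denominator == 0.0:
        return 1.0 if dag.resolve(i) == dag.resolve(j) else 0.0
    return numerator / denominator


def semantic_similarity_matrix(
    dag: DiseaseDAG, diseases: list[str], model: str, delta: float = 0.5
) -> SimilarityMatrix:
    """Pairwise semantic similarity over the covered diseases."""
    k = len(diseases)
    values = np.ones((k, k))
    contributions = {}
    closures = {}
    for name in diseases:
        closures[name] = dag.ancestor_closure(name)
        if model == "wang":
            contributions[name] = semantic_contribution_wang(dag, name, delta)
        else:
            contributions[name] = {
                t: semantic_contribution_xuan(dag, t) for t in closures[name]
            }
    totals = {name: sum(sc.values()) for name, sc in contributions.items()}
    for a in range(k):
        for b in range(a + 1, k):
            da, db = diseases[a], diseases[b]
            shared = closures[da] & closures[db]
            if shared:
                num = sum(contributions[da][t] + contributions[db][t] for t in shared)
                den = totals[da] + totals[db]
                values[a, b] = values[b, a] = num / den if den > 0 else 0.0
            else:
                values[a, b] = values[b, a] = 0.0
    np.clip(values, 0.0, 1.0, out=values)
    return SimilarityMatrix(values, list(diseases), curated_mask=np.ones((k, k), bool))


def fuse_disease_similarity(
    DS1: SimilarityMatrix,
    DS2: SimilarityMatrix,
    GDS: SimilarityMatrix,
    covered: set[str],
) -> SimilarityMatrix:
    """Average of the two semantic models where both diseases are covered,
    Gaussian kernel otherwise."""
    if list(DS1.ids) != list(DS2.ids):
        raise DataError("the two semantic similarity matrices must share labels")
    if not covered <= set(DS1.ids):
        raise DataError("covered diseases must be present in the semantic matrices")
    keep = [name for name in DS1.ids if name in covered]
    if keep:
        sel = np.array([DS1.ids.index(name) for name in keep], dtype=int)
        averaged = SimilarityMatrix(
            0.5 * (DS1.values + DS2.values)[np.ix_(sel, sel)],
            keep,
            curated_mask=np.ones((len(keep), len(keep)), bool),
        )
    else:
        averaged = None
    return _fuse_curated(averaged, GDS, "disease similarity")
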