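"""Glue that assembles both similarity matrices from an association matrix
plus whatever curated side information is available."""

from __future__ import annotations

from dataclasses import dataclass

from .similarity import (
    fuse_disease_similarity,
    fuse_mirna_similarity,
    gaussian_profile_similarity,
    semantic_similarity_matrix,
)
from .types import AssociationMatrix, DiseaseDAG, SimilarityMatrix

__all__ = ["SideInformation", "build_similarities"]


@dataclass
class SideInformation:
    """Optional curated inputs: a functional-similarity table for the row
    entities and a disease hierarchy for the column entities."""

    mirna_functional: SimilarityMatrix | None = None
    disease_dag: DiseaseDAG | None = None
    wang_delta: float = 0.5


def build_similarities(
    Y: AssociationMatrix, side: SideInformation | None = None
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Sm and Sd for a (training) association matrix.

    Gaussian kernels always come from ``Y`` itself, so similarity matrices
    built from a fold's training matrix never see held-out labels.
    """
    side = side or SideInformation()
    GMS = gaussian_profile_similarity(Y, "mirna")
    Sm = fuse_mirna_similarity(side.mirna_functional, GMS)
    GDS = gaussian_profile_similarity(Y, "disease")
    if side.disease_dag is not None:
        covered = [d for d in Y.disease_ids if d in side.disease_dag.disease_roots]
        if covered:
            DS1 = semantic_similarity_matrix(
                side.disease_dag, covered, "wang", side.wang_delta
            )
            DS2 = semantic_similarity_matrix(side.disease_dag, covered, "xuan")
            Sd = fuse_disease_similarity(DS1, DS2, GDS, set(covered))
        else:
            Sd = fuse_disease_similarity_empty(GDS)
    else:
        Sd = fuse_mirna_similarity(None, GDS)
    return Sm, Sd


def fuse_disease_similarity_empty(GDS: SimilarityMatrix) -> SimilarityMatrix:
    return fuse_mirna_similarity(None, GDS)
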