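"""Symmetric degree normalization of similarity matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .types import SimilarityMatrix

__all__ = ["NormalizedGraph", "normalize_adjacency"]


@dataclass
class NormalizedGraph:
    """D^{-1/2} S D^{-1/2} together with the node degrees and labels."""

    adjacency: np.ndarray
    degree: np.ndarray
    ids: list[str]


def normalize_adjacency(S: SimilarityMatrix) -> NormalizedGraph:
    """Scale entry (i, j) by the inverse square root of both row sums.

    The unit diagonal of a valid similarity matrix guarantees strictly
    positive degrees; a zero row sum therefore flags malformed input.
    """
    degree = S.values.sum(axis=1)
    if (degree <= 0.0).any():
        raise DataError("zero row sum: cannot normalize adjacency")
    inv_sqrt = 1.0 / np.sqrt(degree)
    adjacency = S.values * np.outer(inv_sqrt, inv_sqrt)
    return NormalizedGraph(adjacency=adjacency, degree=degree, ids=list(S.ids))
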