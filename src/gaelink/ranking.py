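"""Per-disease candidate ranking over the unknown entries of Y."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .types import AssociationMatrix

__all__ = ["RankedPrediction", "rank_candidates", "write_rankings"]


@dataclass(frozen=True)
class RankedPrediction:
    disease_id: str
    mirna_id: str
    score: float
    rank: int


def rank_candidates(
    F: np.ndarray, Y: AssociationMatrix, k: int = 50
) -> list[RankedPrediction]:
    """Top-k unknown candidates per disease, by descending score.

    Known associations (Y == 1) never appear. Ties break on the miRNA
    identifier lexicographically, which makes the output deterministic.
    """
    if F.shape != Y.values.shape:
        raise DataError(f"score shape {F.shape} does not match associations")
    if k < 1:
        raise DataError("k must be at least 1")
    out: list[RankedPrediction] = []
    for j, disease in enumerate(Y.disease_ids):
        unknown = np.where(Y.values[:, j] == 0)[0]
        candidates = sorted(
            ((float(F[i, j]), Y.mirna_ids[i]) for i in unknown),
            key=lambda pair: (-pair[0], pair[1]),
        )
        for rank, (score, mirna) in enumerate(candidates[:k], start=1):
            out.append(RankedPrediction(disease, mirna, score, rank))
    return out


def write_rankings(path: str | Path, predictions: list[RankedPrediction]) -> None:
    frame = pd.DataFrame(
        {
            "disease_id": [p.disease_id for p in predictions],
            "rank": [p.rank for p in predictions],
            "mirna_id": [p.mirna_id for p in predictions],
            "score": [p.score for p in predictions],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
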