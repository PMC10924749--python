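"""Keypoint matching by thresholded cosine similarity.

Because descriptor rows are unit vectors, the full cosine-similarity
matrix between a query feature matrix Q (n1 x 128) and a key feature
matrix K (n2 x 128) is the single matrix product Q @ K.T. A query
keypoint counts as matched when at least one target similarity exceeds
the threshold t; each matched keypoint contributes its best
above-threshold margin (best similarity minus t) to the match score.

The comparison is intentionally asymmetric: m counts *query* rows, so
swapping Q and K can change (m, s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, ParameterError
from .features import FeatureMatrix

__all__ = ["MatchResult", "cosine_similarity_matrix", "match_features"]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one query-vs-target comparison.

    ``m`` is the matched-keypoint count (0 <= m <= n_query) and ``s`` the
    match score; m == 0 iff s == 0. For non-negative unit descriptors
    s <= m * (1 - t).
    """

    query_id: str
    target_id: str
    m: int
    s: float
    t: float
    n_query: int
    n_target: int


def cosine_similarity_matrix(Q: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities between unit-norm descriptor rows.

    Accumulates in 64-bit floats regardless of storage precision so sums
    are deterministic across platforms.
    """
    Q = np.asarray(Q, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    if Q.ndim != 2 or K.ndim != 2:
        raise InvalidInputError("descriptor matrices must be 2D")
    if Q.shape[1] != K.shape[1]:
        raise InvalidInputError(
            f"descriptor widths differ: {Q.shape[1]} vs {K.shape[1]}"
        )
    for name, mat in (("Q", Q), ("K", K)):
        if mat.shape[0]:
            norms = np.linalg.norm(mat, axis=1)
            if np.abs(norms - 1.0).max() > _UNIT_TOL:
                raise InvalidInputError(
                    f"rows of {name} are not unit-norm within {_UNIT_TOL}"
                )
    return Q @ K.T


def match_features(
    Q: FeatureMatrix, K: FeatureMatrix, t: float = 0.9
) -> MatchResult:
    """Match every query keypoint against a target feature matrix.

    For each row of the similarity matrix M = Q @ K.T, entries at or
    below ``t`` are discarded; if any entry survives, the match count m
    increments and the row's best margin max(M_row) - t accrues to the
    match score s. Empty Q or K trivially yields (0, 0.0).

    Parameters
    ----------
    Q, K : FeatureMatrix
        Query and target descriptors (rows unit-norm).
    t : float
        Similarity threshold in [0, 1). The default 0.9 is conservative
        for non-negative unit descriptors, whose random similarities
        concentrate well below it.
    """
    if not (0.0 <= t < 1.0):
        raise ParameterError(f"threshold t must be in [0, 1), got {t}")
    if Q.n_features == 0 or K.n_features == 0:
        return MatchResult(
            query_id=Q.id, target_id=K.id, m=0, s=0.0, t=t,
            n_query=Q.n_features, n_target=K.n_features,
        )
    M = cosine_similarity_matrix(Q.descriptors, K.descriptors)
    above = M > t
    matched_rows = above.any(axis=1)
    m = int(matched_rows.sum())
    if m:
        margins = np.where(above, M - t, 0.0)
        s = float(margins[matched_rows].max(axis=1).sum())
    else:
        s = 0.0
    return MatchResult(
        query_id=Q.id, target_id=K.id, m=m, s=s, t=t,
        n_query=Q.n_features, n_target=K.n_features,
    )
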