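"""Functional similarity of circRNAs via disease-association score vectors.

Each circRNA c in the association set C is embedded in the space spanned by
the circRNA-related diseases D: its coordinate on disease *dis* is

    Score(dis, c) = 1                                if dis ∈ DisSet(c)
                    max_{dis_i ∈ DisSet(c)} dsim(dis, dis_i)  otherwise

where DisSet(c) are the diseases curated for c and dsim is an externally
supplied disease–disease similarity matrix. Filling every cell this way
counters the sparsity of curated associations. Functional similarity between
two circRNAs is then the cosine of their score vectors, which lies in [0, 1]
because scores are nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from precda.errors import PrecdaError
from precda.ingest import AssociationDB, DiseaseSimilarityMatrix


@dataclass
class DiseaseScoreMatrix:
    """Dense |C| × |D| matrix of association scores in [0, 1]."""

    circ_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.circ_ids), len(self.disease_ids)):
            raise PrecdaError("score matrix shape mismatch")
        self._circ_index = {c: i for i, c in enumerate(self.circ_ids)}

    def row(self, circ: str) -> np.ndarray:
        return self.values[self._circ_index[circ]]


@dataclass
class FunctionalSimilarityMatrix:
    """Symmetric circRNA × circRNA cosine similarity matrix in [0, 1]."""

    circ_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.circ_ids)
        if self.values.shape != (n, n):
            raise PrecdaError("functional similarity matrix must be square")
        self._index = {c: i for i, c in enumerate(self.circ_ids)}

    def __contains__(self, circ: str) -> bool:
        return circ in self._index

    def loc(self, circ_a: str, circ_b: str) -> float:
        return float(self.values[self._index[circ_a], self._index[circ_b]])


def score_disease_circrna(
    dis: str, c: str, assoc: AssociationDB, dsim: DiseaseSimilarityMatrix
) -> float:
    """Association score between disease *dis* and circRNA *c*.

    1 for a curated association; otherwise the maximum similarity between
    *dis* and any disease curated for *c*.
    """
    disset = assoc.disset(c)
    if not disset:
        raise PrecdaError(f"circRNA {c!r} has no curated disease (not in set C)")
    if dis not in dsim:
        raise PrecdaError(f"disease {dis!r} absent from similarity matrix")
    if dis in disset:
        return 1.0
    row = dsim.row(dis)
    score = max(float(row[dsim.disease_ids.index(d)]) for d in disset)
    return score


def build_score_matrix(
    assoc: AssociationDB, dsim: DiseaseSimilarityMatrix
) -> DiseaseScoreMatrix:
    """Score every (circRNA, disease) cell of C × D.

    D is the set of circRNA-related diseases in *assoc* (not the full
    ontology). Curated cells are exactly 1; the rest carry the max-similarity
    score, so every row has at least one 1.
    """
    circ_ids = sorted(assoc.circ_ids)
    disease_ids = sorted(assoc.disease_ids)
    missing = [d for d in disease_ids if d not in dsim]
    if missing:
        raise PrecdaError(f"diseases absent from similarity matrix: {missing}")
    dcol = {d: dsim.disease_ids.index(d) for d in disease_ids}
    sub = dsim.values[np.ix_([dcol[d] for d in disease_ids], [dcol[d] for d in disease_ids])]
    values = np.empty((len(circ_ids), len(disease_ids)))
    col_of = {d: j for j, d in enumerate(disease_ids)}
    for i, c in enumerate(circ_ids):
        members = [col_of[d] for d in assoc.disset(c)]
        values[i] = sub[:, members].max(axis=1)
        values[i, members] = 1.0
    return DiseaseScoreMatrix(circ_ids, disease_ids, values)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of two score vectors, clamped to [0, 1].

    Returns NaN for a zero vector (cannot occur for genuine score rows,
    where curated associations score 1, but kept defensive).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise PrecdaError("score vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(np.clip(np.dot(u, v) / (nu * nv), 0.0, 1.0))


def functional_similarity_matrix(scores: DiseaseScoreMatrix) -> FunctionalSimilarityMatrix:
    """All-pairs cosine similarity of score rows; symmetric, unit diagonal."""
    if len(scores.circ_ids) < 2:
        raise PrecdaError("need at least two circRNAs")
    norms = np.linalg.norm(scores.values, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise PrecdaError("zero score row encountered")
    unit = scores.values / norms
    sim = np.clip(unit @ unit.T, 0.0, 1.0)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return FunctionalSimilarityMatrix(list(scores.circ_ids), sim)
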