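"""Expression similarity: Spearman correlation per source, max-combined, thresholded.

Each source contributes a raw circRNA × circRNA matrix of Spearman rank
correlations across that source's own conditions. The two sources are then
combined pairwise by maximum and a threshold τ (default 0.7) zeroes weak
similarities:

    ExSim(i, j) = max(CB(i, j), CP(i, j))  if that max >= τ, else 0

Ties get average ranks (so the correlation is the Pearson correlation of the
rank vectors), which reduces exactly to the classical closed form
ρ = 1 − 6 Σ dᵢ² / (n(n² − 1)) when no ties exist. Pairs with fewer than
three shared non-missing conditions, or a constant profile, have undefined
similarity (NaN in the raw stage), which the combined stage treats as
absent — indistinguishable from filtered-out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from precda.errors import ParameterError, PrecdaError
from precda.ingest import ExpressionProfileSet

MIN_SHARED_CONDITIONS = 3

RAW = "raw"
COMBINED = "combined-thresholded"


@dataclass
class ExpressionSimilarityMatrix:
    """Symmetric circRNA × circRNA similarity matrix.

    stage "raw": entries in [−1, 1] or NaN (undefined), unit diagonal.
    stage "combined-thresholded": entries in {0} ∪ [τ, 1].
    """

    circ_ids: list[str]
    values: np.ndarray
    stage: str
    tau: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.circ_ids)
        if self.values.shape != (n, n):
            raise PrecdaError("similarity matrix must be square over circ_ids")
        self._index = {c: i for i, c in enumerate(self.circ_ids)}

    def __contains__(self, circ: str) -> bool:
        return circ in self._index

    def loc(self, circ_a: str, circ_b: str) -> float:
        return float(self.values[self._index[circ_a], self._index[circ_b]])


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation over pairwise-complete positions.

    Returns NaN (undefined similarity) when fewer than three shared
    non-missing positions remain or either vector is constant on them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PrecdaError("profiles must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if int(ok.sum()) < MIN_SHARED_CONDITIONS:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan")
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho)


def source_similarity_matrix(profiles: ExpressionProfileSet) -> ExpressionSimilarityMatrix:
    """All-pairs Spearman similarity for one expression source (raw stage)."""
    n = len(profiles.circ_ids)
    if n < 2:
        raise PrecdaError("need at least two circRNAs for a similarity matrix")
    vals = np.where(profiles.mask, np.nan, profiles.values)

    complete = not np.isnan(vals).any()
    constant = np.array([np.nanstd(row) == 0 or np.isnan(row).all() for row in vals])
    if complete and not constant.any() and vals.shape[1] >= MIN_SHARED_CONDITIONS:
        ranks = stats.rankdata(vals, axis=1)
        out = np.corrcoef(ranks)
    else:
        out = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = spearman_rho(vals[i], vals[j])
    np.fill_diagonal(out, 1.0)
    return ExpressionSimilarityMatrix(list(profiles.circ_ids), out, stage=RAW)


def combine_and_threshold(
    cb: ExpressionSimilarityMatrix,
    cp: ExpressionSimilarityMatrix | None,
    tau: float = 0.7,
    both_sources_only: bool = False,
) -> ExpressionSimilarityMatrix:
    """Combine per-source raw matrices by maximum and apply the τ filter.

    Pairs measured in both sources take the larger of the two correlations;
    pairs measured in only one source keep that source's value unless
    ``both_sources_only`` enforces the strict both-sources reading (then they
    become 0). Undefined (NaN) raw entries count as unmeasured. The output
    covers the union of the two ID sets with entries in {0} ∪ [τ, 1].
    """
    if not (0 < tau <= 1):
        raise ParameterError(f"tau must lie in (0, 1], got {tau}")
    for m in (cb, cp):
        if m is not None and m.stage != RAW:
            raise ParameterError("combine_and_threshold expects raw-stage matrices")

    ids = sorted(set(cb.circ_ids) | (set(cp.circ_ids) if cp is not None else set()))
    n = len(ids)

    def expand(m: ExpressionSimilarityMatrix | None) -> np.ndarray:
        full = np.full((n, n), np.nan)
        if m is None:
            return full
        idx = np.array([ids.index(c) for c in m.circ_ids])
        full[np.ix_(idx, idx)] = m.values
        return full

    a, b = expand(cb), expand(cp)
    both = ~np.isnan(a) & ~np.isnan(b)
    either = ~np.isnan(a) | ~np.isnan(b)
    combined = np.where(both, np.fmax(a, b), np.where(either, np.fmax(a, b), np.nan))
    if both_sources_only:
        combined = np.where(both, combined, np.nan)
    out = np.where(np.isnan(combined) | (combined < tau), 0.0, combined)
    np.fill_diagonal(out, 1.0)
    return ExpressionSimilarityMatrix(ids, out, stage=COMBINED, tau=tau)
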