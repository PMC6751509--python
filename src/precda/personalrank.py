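"""PersonalRank: random walk with restart at a single target node.

The walker sits at the target disease, follows an incident edge with
probability d (0.85 by default) or restarts at the target with probability
1 − d. The stationary solution of

    PR(i) = (1 − d) r_i + d Σ_{j → i} PR(j) p(j → i),   r = e_target

scores every node's relevance to the target. Transition probabilities are
edge weights normalised by each node's total incident weight, which reduces
to the classical 1/out-degree rule on unweighted graphs (the
``unweighted`` flag restores that literal reading). Fixed-point iteration
starts at PR⁰ = r and stops when the L∞ change drops below ``tol``; a dense
linear solve of the same fixed point is provided as an exact cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from precda.errors import ParameterError, PrecdaError
from precda.ingest import AssociationDB
from precda.network import CIRC


@dataclass(frozen=True)
class WalkParams:
    """Walk hyperparameters: transfer probability d, tolerance, iteration cap."""

    d: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self):
        if not (0 < self.d < 1):
            raise ParameterError(f"transfer probability d must lie in (0, 1), got {self.d}")
        if self.tol <= 0:
            raise ParameterError("tol must be positive")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")


@dataclass
class RankResult:
    """Scores and candidate ranking for one target disease.

    ``candidate_ranking`` lists circRNAs not curated for the target,
    descending by score with lexicographic tie-break on the ID.
    """

    target: str
    scores: dict[str, float]
    candidate_ranking: list[tuple[str, float]]
    iterations_used: int
    converged: bool
    params: WalkParams = field(default_factory=WalkParams)


def _node_order(g: nx.Graph) -> list[str]:
    return sorted(g.nodes)


def transition_matrix(
    g: nx.Graph, order: list[str] | None = None, unweighted: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Row-stochastic transition matrix P with P[j, i] = w(j,i) / Σ_k w(j,k).

    Rows of isolated nodes are all-zero: a walker there loses its mass,
    which the restart term replenishes at the target.
    """
    order = order or _node_order(g)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    w = np.zeros((n, n))
    for a, b, data in g.edges(data=True):
        weight = 1.0 if unweighted else float(data.get("weight", 1.0))
        if weight < 0:
            raise PrecdaError(f"negative edge weight on ({a}, {b})")
        w[idx[a], idx[b]] = weight
        w[idx[b], idx[a]] = weight
    totals = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, w / totals, 0.0)
    return p, order


def personal_rank(
    g: nx.Graph,
    target: str,
    params: WalkParams | None = None,
    unweighted: bool = False,
) -> RankResult:
    """Iterate the restart walk from *target* to stationarity.

    Non-convergence within ``max_iter`` is flagged on the result, not
    raised. The candidate ranking excludes circRNAs already linked to the
    target by an association edge.
    """
    params = params or WalkParams()
    if target not in g:
        raise PrecdaError(f"target node {target!r} not in network")
    p, order = transition_matrix(g, unweighted=unweighted)
    idx = {n: i for i, n in enumerate(order)}
    r = np.zeros(len(order))
    r[idx[target]] = 1.0

    pr = r.copy()
    converged = False
    iterations = 0
    pt = p.T
    for iterations in range(1, params.max_iter + 1):
        nxt = (1 - params.d) * r + params.d * (pt @ pr)
        if np.max(np.abs(nxt - pr)) < params.tol:
            pr = nxt
            converged = True
            break
        pr = nxt

    scores = {node: float(pr[idx[node]]) for node in order}
    known = {
        nb
        for nb in g.neighbors(target)
        if g.edges[target, nb].get("kind") == "cd" and g.nodes[nb]["kind"] == CIRC
    }
    candidates = [
        (node, scores[node])
        for node in order
        if g.nodes[node]["kind"] == CIRC and node not in known
    ]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return RankResult(
        target=target,
        scores=scores,
        candidate_ranking=candidates,
        iterations_used=iterations,
        converged=converged,
        params=params,
    )


def personal_rank_exact(
    g: nx.Graph,
    target: str,
    params: WalkParams | None = None,
    unweighted: bool = False,
) -> dict[str, float]:
    """Exact stationary scores via the dense linear system (I − d Pᵀ) PR = (1 − d) r."""
    params = params or WalkParams()
    if target not in g:
        raise PrecdaError(f"target node {target!r} not in network")
    p, order = transition_matrix(g, unweighted=unweighted)
    n = len(order)
    r = np.zeros(n)
    r[order.index(target)] = 1.0
    pr = np.linalg.solve(np.eye(n) - params.d * p.T, (1 - params.d) * r)
    return {node: float(pr[i]) for i, node in enumerate(order)}


def rank_candidates(result: RankResult, assoc: AssociationDB) -> list[tuple[str, float]]:
    """Re-derive the candidate ranking from an association database.

    Removes circRNAs curated for the target disease in *assoc* and sorts the
    rest descending by score, ties broken lexicographically by ID.
    """
    known = assoc.circset(result.target)
    ranked = [
        (c, s)
        for c, s in result.scores.items()
        if c in assoc.circ_ids and c not in known
    ]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked
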