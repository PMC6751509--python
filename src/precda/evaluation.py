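"""Cross-database validation: held-out positives, per-disease AUC, sweeps.

The validation scheme plays two curated databases against each other: the
network is built from database A, and any (circRNA, disease) pair curated in
reference database B — where the circRNA is a node of A's network but the
pair itself is absent from A — becomes a held-out positive. For each such
disease the walk ranks every circRNA not curated for it in A, and the AUC of
the held-out positives within that ranking (rank-sum / Mann–Whitney
estimator) measures how far known-elsewhere associations rise above the
background. Per-disease AUCs are macro-averaged (unweighted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from precda.errors import ParameterError, PrecdaError
from precda.expression import ExpressionSimilarityMatrix, combine_and_threshold, source_similarity_matrix
from precda.functional import build_score_matrix, functional_similarity_matrix
from precda.ingest import AssociationDB, DiseaseSimilarityMatrix, ExpressionProfileSet
from precda.network import assemble_network
from precda.personalrank import WalkParams, personal_rank


@dataclass(frozen=True)
class TestCase:
    """Held-out positives for one disease in one network/reference pairing."""

    disease: str
    positives: tuple[str, ...]
    network_db: str
    reference_db: str


@dataclass
class EvaluationReport:
    """Per-disease AUC table plus the macro-average summary."""

    per_disease: pd.DataFrame  # columns: disease, n_positives, n_candidates, auc
    network_db: str
    reference_db: str

    @property
    def macro_auc(self) -> float:
        if self.per_disease.empty:
            return float("nan")
        return float(self.per_disease["auc"].mean())

    @property
    def disease_aucs(self) -> dict[str, float]:
        return dict(zip(self.per_disease["disease"], self.per_disease["auc"]))

    def summary(self) -> str:
        lines = [
            f"network DB     : {self.network_db}",
            f"reference DB   : {self.reference_db}",
            f"test diseases  : {len(self.per_disease)}",
            f"macro-avg AUC  : {self.macro_auc:.4f}",
        ]
        return "\n".join(lines)


def extract_test_cases(
    network_db: AssociationDB, reference_db: AssociationDB
) -> list[TestCase]:
    """Held-out positives per disease shared by the two databases.

    A circRNA qualifies when it is a node of the network built from
    ``network_db`` (i.e. a member of its circRNA set), the pair is curated in
    ``reference_db``, and the pair is absent from ``network_db``. Diseases
    with no qualifying circRNA are omitted.
    """
    cases = []
    network_circ = network_db.circ_ids
    for disease in sorted(network_db.disease_ids & reference_db.disease_ids):
        positives = sorted(
            c
            for c in reference_db.circset(disease)
            if c in network_circ and (c, disease) not in network_db.pairs
        )
        for c in positives:  # invariant, not merely tested
            assert (c, disease) not in network_db.pairs
        if positives:
            cases.append(
                TestCase(
                    disease=disease,
                    positives=tuple(positives),
                    network_db=network_db.label,
                    reference_db=reference_db.label,
                )
            )
    return cases


def auc_from_ranking(
    ranking: Sequence[tuple[str, float]], positives: Sequence[str]
) -> float:
    """Rank-sum (Mann–Whitney) AUC of *positives* within a scored ranking.

    Equals the fraction of (positive, negative) pairs where the positive
    scores higher, counting score ties as half. NaN when the ranking holds
    no positive or no negative.
    """
    members = {c for c, _ in ranking}
    stray = set(positives) - members
    if stray:
        raise PrecdaError(f"positives not present in ranking: {sorted(stray)}")
    pos = set(positives)
    scores = np.array([s for _, s in ranking], dtype=float)
    is_pos = np.array([c in pos for c, _ in ranking])
    n_pos = int(is_pos.sum())
    n_neg = len(ranking) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)  # ascending, average ranks for ties
    auc = (ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def _build_exsim(
    expr_sets: Sequence[ExpressionProfileSet] | None,
    tau: float,
    both_sources_only: bool,
) -> ExpressionSimilarityMatrix | None:
    if not expr_sets:
        return None
    if len(expr_sets) > 2:
        raise ParameterError("at most two expression sources are supported")
    raws = [source_similarity_matrix(e) for e in expr_sets]
    cb = raws[0]
    cp = raws[1] if len(raws) == 2 else None
    return combine_and_threshold(cb, cp, tau=tau, both_sources_only=both_sources_only)


def run_validation(
    network_db: AssociationDB,
    reference_db: AssociationDB,
    expr_sets: Sequence[ExpressionProfileSet] | None,
    dsim: DiseaseSimilarityMatrix,
    params: WalkParams | None = None,
    tau: float = 0.7,
    both_sources_only: bool = False,
    unweighted: bool = False,
) -> EvaluationReport:
    """Run the full pipeline for one (network DB, reference DB) pairing.

    Builds functional similarity from ``network_db`` and ``dsim``, expression
    similarity from up to two sources, assembles the network, extracts the
    held-out test cases against ``reference_db``, ranks candidates per test
    disease with the restart walk, and scores one AUC per disease over all of
    its positives jointly.
    """
    params = params or WalkParams()
    scores = build_score_matrix(network_db, dsim)
    fnsim = functional_similarity_matrix(scores)
    exsim = _build_exsim(expr_sets, tau, both_sources_only)
    net = assemble_network(fnsim, exsim, network_db)
    cases = extract_test_cases(network_db, reference_db)

    rows = []
    for case in cases:
        result = personal_rank(net, case.disease, params, unweighted=unweighted)
        auc = auc_from_ranking(result.candidate_ranking, case.positives)
        rows.append(
            {
                "disease": case.disease,
                "n_positives": len(case.positives),
                "n_candidates": len(result.candidate_ranking),
                "auc": auc,
            }
        )
    per_disease = pd.DataFrame(rows, columns=["disease", "n_positives", "n_candidates", "auc"])
    return EvaluationReport(
        per_disease=per_disease,
        network_db=network_db.label,
        reference_db=reference_db.label,
    )


def ablation_cosine_only(
    network_db: AssociationDB,
    reference_db: AssociationDB,
    dsim: DiseaseSimilarityMatrix,
    params: WalkParams | None = None,
    unweighted: bool = False,
) -> EvaluationReport:
    """Validation with expression evidence removed: edges carry FnSim alone."""
    return run_validation(
        network_db,
        reference_db,
        expr_sets=None,
        dsim=dsim,
        params=params,
        unweighted=unweighted,
    )


def threshold_sweep(
    taus: Sequence[float],
    network_db: AssociationDB,
    reference_db: AssociationDB,
    expr_sets: Sequence[ExpressionProfileSet],
    dsim: DiseaseSimilarityMatrix,
    params: WalkParams | None = None,
    both_sources_only: bool = False,
) -> pd.DataFrame:
    """Re-run the full validation at each τ.

    Returns one row per τ with the macro-AUC and the count of nonzero
    off-diagonal entries surviving the filter (non-increasing in τ).
    """
    for tau in taus:
        if not (0 < tau <= 1):
            raise ParameterError(f"tau must lie in (0, 1], got {tau}")
    rows = []
    for tau in taus:
        exsim = _build_exsim(expr_sets, tau, both_sources_only)
        nonzero = int(np.count_nonzero(exsim.values) - len(exsim.circ_ids))
        report = run_validation(
            network_db,
            reference_db,
            expr_sets,
            dsim,
            params=params,
            tau=tau,
            both_sources_only=both_sources_only,
        )
        rows.append(
            {
                "tau": tau,
                "macro_auc": report.macro_auc,
                "n_nonzero_exsim": nonzero,
                "n_test_diseases": len(report.per_disease),
            }
        )
    return pd.DataFrame(rows)


def summarize_experiments(reports: Sequence[EvaluationReport]) -> dict[str, float]:
    """Average AUC across validation experiments, both readings.

    ``macro_of_macros`` averages each experiment's macro-AUC; ``pooled``
    averages every disease-level AUC across all experiments.
    """
    macros = [r.macro_auc for r in reports if not np.isnan(r.macro_auc)]
    pooled = [
        a
        for r in reports
        for a in r.per_disease["auc"].tolist()
        if not np.isnan(a)
    ]
    return {
        "macro_of_macros": float(np.mean(macros)) if macros else float("nan"),
        "pooled": float(np.mean(pooled)) if pooled else float("nan"),
    }
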