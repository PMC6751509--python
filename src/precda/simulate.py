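"""Synthetic fixtures with planted circRNA–disease modules.

The generator emulates the statistical structure the pipeline exploits:
groups of circRNAs that are co-expressed *and* attached to the same cluster
of related diseases. Each module k gets a latent expression factor f_k; a
member circRNA's underlying profile is

    x_i = sqrt(ρ) f_k + sqrt(1 − ρ) ε_i,    ε_i ~ N(0, 1) i.i.d.

so any two same-module profiles have expected Pearson (hence asymptotic
Spearman) correlation ρ, while cross-module profiles are uncorrelated. Two
pseudo-sources each observe an overlapping subset of circRNAs with
independent measurement noise, exercising the max-combination and the
single-source branch of the τ filter. Disease similarity is generated
directly as a block matrix (high within modules, low between); associations
are drawn within modules at a configurable density, and a fraction of the
true pairs is held out to the reference database only, creating valid
cross-database test cases with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from precda.errors import ParameterError
from precda.ingest import (
    AssociationDB,
    DiseaseSimilarityMatrix,
    ExpressionProfileSet,
    read_association_table,
    read_disease_similarity,
    read_expression_matrix,
    write_association_table,
    write_disease_similarity,
    write_expression_matrix,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic bundle.

    Defaults describe the strong-signal desk-scale scenario: five modules of
    ten circRNAs and three diseases each, 20 conditions per source, high
    within-module expression correlation and disease similarity, dense
    within-module associations with a fifth held out.
    """

    n_modules: int = 5
    circ_per_module: int = 10
    dis_per_module: int = 3
    n_conditions: int = 20
    within_module_expr_corr: float = 0.9
    noise_sd: float = 0.3
    within_module_dsim: float = 0.9
    between_module_dsim: float = 0.1
    assoc_density: float = 0.8
    assoc_noise: float = 0.0
    holdout_fraction: float = 0.2
    source_overlap: float = 0.6
    random_associations: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.within_module_expr_corr < 1):
            raise ParameterError("within_module_expr_corr must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if not (0 < self.within_module_dsim <= 1):
            raise ParameterError("within_module_dsim must lie in (0, 1]")
        if not (0 <= self.between_module_dsim <= self.within_module_dsim):
            raise ParameterError(
                "between_module_dsim must lie in [0, within_module_dsim]"
            )
        if (
            not self.random_associations
            and self.between_module_dsim >= self.within_module_dsim
        ):
            raise ParameterError(
                "between_module_dsim must be strictly below within_module_dsim"
            )
        if not (0 < self.assoc_density <= 1):
            raise ParameterError("assoc_density must lie in (0, 1]")
        if not (0 <= self.assoc_noise < 1):
            raise ParameterError("assoc_noise must lie in [0, 1)")
        if not (0 <= self.holdout_fraction < 1):
            raise ParameterError("holdout_fraction must lie in [0, 1)")
        if not (0 <= self.source_overlap <= 1):
            raise ParameterError("source_overlap must lie in [0, 1]")
        if min(self.n_modules, self.circ_per_module, self.dis_per_module) < 1:
            raise ParameterError("module counts must be positive")
        if self.n_conditions < 3:
            raise ParameterError("need at least three conditions per source")


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Signal-free conditions: uncorrelated expression, flat disease
    similarity, associations drawn without regard to modules."""
    base = dict(
        within_module_expr_corr=0.0,
        within_module_dsim=0.5,
        between_module_dsim=0.5,
        random_associations=True,
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def expression_informative_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Conditions under which expression carries information the curated
    associations lack: a third of associations are rewired across modules
    (curation noise) and the disease-similarity contrast is modest, so the
    functional channel alone separates modules imperfectly while expression
    profiles remain cleanly module-structured."""
    base = dict(
        assoc_noise=0.3,
        within_module_dsim=0.3,
        between_module_dsim=0.05,
        assoc_density=0.5,
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass
class Bundle:
    """One generated instance plus its ground truth."""

    expr_a: ExpressionProfileSet
    expr_b: ExpressionProfileSet
    network_db: AssociationDB
    reference_db: AssociationDB
    dsim: DiseaseSimilarityMatrix
    module_of_circ: dict[str, int]
    module_of_disease: dict[str, int]
    config: GeneratorConfig


def _circ_id(k: int) -> str:
    return f"hsa_circ_{k + 1:07d}"


def _disease_id(k: int) -> str:
    return f"DOID:{9000 + k}"


def generate(config: GeneratorConfig) -> Bundle:
    """Draw one bundle under *config*; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_circ = config.n_modules * config.circ_per_module
    n_dis = config.n_modules * config.dis_per_module
    circ_ids = [_circ_id(i) for i in range(n_circ)]
    disease_ids = [_disease_id(i) for i in range(n_dis)]
    module_of_circ = {c: i // config.circ_per_module for i, c in enumerate(circ_ids)}
    module_of_disease = {d: i // config.dis_per_module for i, d in enumerate(disease_ids)}

    # latent-factor expression: shared module factor + independent noise
    rho = config.within_module_expr_corr
    factors = rng.standard_normal((config.n_modules, config.n_conditions))
    eps = rng.standard_normal((n_circ, config.n_conditions))
    base = np.sqrt(rho) * factors[[module_of_circ[c] for c in circ_ids]] + np.sqrt(
        1 - rho
    ) * eps

    # two pseudo-sources over overlapping circRNA subsets
    n_obs = int(round(n_circ * (1 + config.source_overlap) / 2))
    n_obs = min(max(n_obs, 2), n_circ)
    perm = rng.permutation(n_circ)
    idx_a = np.sort(perm[:n_obs])
    idx_b = np.sort(perm[n_circ - n_obs :])

    def observe(idx: np.ndarray, tag: str) -> ExpressionProfileSet:
        noisy = base[idx] + config.noise_sd * rng.standard_normal(
            (len(idx), config.n_conditions)
        )
        return ExpressionProfileSet(
            source=tag,
            circ_ids=[circ_ids[i] for i in idx],
            conditions=[f"{tag}_cond_{j + 1:02d}" for j in range(config.n_conditions)],
            values=noisy,
        )

    expr_a = observe(idx_a, "sourceA")
    expr_b = observe(idx_b, "sourceB")

    # block-structured disease similarity
    dvals = np.full((n_dis, n_dis), config.between_module_dsim)
    for d, m in module_of_disease.items():
        for e, l in module_of_disease.items():
            if m == l:
                dvals[disease_ids.index(d), disease_ids.index(e)] = config.within_module_dsim
    np.fill_diagonal(dvals, 1.0)
    dsim = DiseaseSimilarityMatrix(disease_ids=list(disease_ids), values=dvals)

    # associations: within-module (or uniform under the null), with an
    # optional curation-noise fraction rewired to another module's diseases
    true_pairs: set[tuple[str, str]] = set()  # module-consistent
    noise_pairs: set[tuple[str, str]] = set()
    for c in circ_ids:
        if config.random_associations:
            pool = disease_ids
        else:
            pool = [d for d in disease_ids if module_of_disease[d] == module_of_circ[c]]
        drawn = [d for d in pool if rng.random() < config.assoc_density]
        if not drawn:  # every circRNA must belong to set C
            drawn = [pool[rng.integers(len(pool))]]
        for d in drawn:
            if not config.random_associations and rng.random() < config.assoc_noise:
                others = [
                    x for x in disease_ids if module_of_disease[x] != module_of_circ[c]
                ]
                noise_pairs.add((c, others[rng.integers(len(others))]))
            else:
                true_pairs.add((c, d))
    all_pairs = true_pairs | noise_pairs

    # hold out a fraction of the module-consistent pairs to the reference
    # database only, never emptying a circRNA's or a disease's last network
    # association
    candidates = sorted(true_pairs)
    rng.shuffle(candidates)
    n_hold = int(round(config.holdout_fraction * len(candidates)))
    circ_left = {c: sum(1 for p in all_pairs if p[0] == c) for c in circ_ids}
    dis_left = {d: sum(1 for p in all_pairs if p[1] == d) for d in disease_ids}
    holdout: set[tuple[str, str]] = set()
    for c, d in candidates:
        if len(holdout) >= n_hold:
            break
        if circ_left[c] > 1 and dis_left[d] > 1:
            holdout.add((c, d))
            circ_left[c] -= 1
            dis_left[d] -= 1

    network_db = AssociationDB(label="synthetic-net", pairs=frozenset(all_pairs - holdout))
    reference_db = AssociationDB(label="synthetic-ref", pairs=frozenset(all_pairs))
    return Bundle(
        expr_a=expr_a,
        expr_b=expr_b,
        network_db=network_db,
        reference_db=reference_db,
        dsim=dsim,
        module_of_circ=module_of_circ,
        module_of_disease=module_of_disease,
        config=config,
    )


def write_bundle(bundle: Bundle, directory: str | Path) -> dict[str, Path]:
    """Write all bundle components as TSV in the dialects the readers accept."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr_a": directory / "expression_sourceA.tsv",
        "expr_b": directory / "expression_sourceB.tsv",
        "network_db": directory / "associations_network.tsv",
        "reference_db": directory / "associations_reference.tsv",
        "dsim": directory / "disease_similarity.tsv",
        "modules": directory / "module_labels.tsv",
    }
    write_expression_matrix(bundle.expr_a, paths["expr_a"])
    write_expression_matrix(bundle.expr_b, paths["expr_b"])
    write_association_table(bundle.network_db, paths["network_db"])
    write_association_table(bundle.reference_db, paths["reference_db"])
    write_disease_similarity(bundle.dsim, paths["dsim"])
    with open(paths["modules"], "w", encoding="utf-8") as fh:
        fh.write("# id\tnode_type\tmodule\n")
        for c, m in sorted(bundle.module_of_circ.items()):
            fh.write(f"{c}\tcircrna\t{m}\n")
        for d, m in sorted(bundle.module_of_disease.items()):
            fh.write(f"{d}\tdisease\t{m}\n")
    return paths


def read_bundle(directory: str | Path, config: GeneratorConfig | None = None) -> Bundle:
    """Read a written bundle back (module labels from the sidecar file)."""
    directory = Path(directory)
    expr_a = read_expression_matrix(directory / "expression_sourceA.tsv", "sourceA")
    expr_b = read_expression_matrix(directory / "expression_sourceB.tsv", "sourceB")
    network_db, _ = read_association_table(
        directory / "associations_network.tsv", label="synthetic-net"
    )
    reference_db, _ = read_association_table(
        directory / "associations_reference.tsv", label="synthetic-ref"
    )
    dsim = read_disease_similarity(directory / "disease_similarity.tsv")
    module_of_circ: dict[str, int] = {}
    module_of_disease: dict[str, int] = {}
    with open(directory / "module_labels.tsv", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            node, kind, module = line.rstrip("\n").split("\t")
            if kind == "circrna":
                module_of_circ[node] = int(module)
            else:
                module_of_disease[node] = int(module)
    return Bundle(
        expr_a=expr_a,
        expr_b=expr_b,
        network_db=network_db,
        reference_db=reference_db,
        dsim=dsim,
        module_of_circ=module_of_circ,
        module_of_disease=module_of_disease,
        config=config or GeneratorConfig(),
    )


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)
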