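"""Reading and harmonising circRNA/disease inputs.

All file dialects are plain text: UTF-8, tab-separated, ``#``-prefixed
comment lines ignored. Association tables hold one (circRNA, disease) pair
per row with an optional third provenance column; expression matrices carry
a condition-name header row and circRNA row labels; disease-similarity
matrices are square with matching header row and column; ontologies arrive
either as OBO or as a flat three-column TSV (id, name, pipe-separated
synonyms).

Identifier harmonisation routes every alias through a :class:`SynonymMap`.
Rows that cannot be mapped are never silently dropped — they are returned in
a rejects report so the audit trail is complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from precda.errors import AmbiguousSynonymError, ParseError, PrecdaError

_NA_TOKENS = {"", "NA", "NaN", "nan", "N/A", "null", "None"}


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, line) skipping comments and blank lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DiseaseTerm:
    """A disease-ontology term: canonical DOID, preferred name, synonyms."""

    ontology_id: str
    name: str
    synonyms: tuple[str, ...] = ()
    xrefs: tuple[str, ...] = ()


class SynonymMap:
    """Functional alias → canonical mapping for circRNA or disease IDs.

    Canonical IDs always map to themselves. An empty map is the identity
    (every ID is taken at face value); a non-empty map is strict — aliases
    it does not know resolve to ``None`` so callers can reject them.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        self._map: dict[str, str] = {}
        for alias, canonical in (mapping or {}).items():
            self.add(alias, canonical)

    def add(self, alias: str, canonical: str) -> None:
        if not alias or not canonical:
            raise PrecdaError("empty alias or canonical ID in synonym map")
        existing = self._map.get(alias)
        if existing is not None and existing != canonical:
            raise AmbiguousSynonymError(
                f"alias {alias!r} maps to both {existing!r} and {canonical!r}"
            )
        self._map[alias] = canonical
        self._map.setdefault(canonical, canonical)

    def resolve(self, alias: str) -> str | None:
        """Canonical ID for *alias*, or None if unmappable (non-empty map)."""
        if not self._map:
            return alias
        return self._map.get(alias)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, alias: str) -> bool:
        return alias in self._map

    def as_dict(self) -> dict[str, str]:
        return dict(self._map)


@dataclass(frozen=True)
class AssociationDB:
    """Curated (circRNA, disease) association pairs from one source.

    ``circ_ids`` is the set C of disease-related circRNAs and
    ``disease_ids`` the set D of circRNA-related diseases — the projections
    of the pair set.
    """

    label: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self):
        for pair in self.pairs:
            if len(pair) != 2 or not pair[0] or not pair[1]:
                raise PrecdaError(f"malformed association pair {pair!r}")

    @property
    def circ_ids(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.pairs)

    @property
    def disease_ids(self) -> frozenset[str]:
        return frozenset(d for _, d in self.pairs)

    def disset(self, circ: str) -> frozenset[str]:
        """DisSet(c): diseases directly associated with circRNA *circ*."""
        return frozenset(d for c, d in self.pairs if c == circ)

    def circset(self, disease: str) -> frozenset[str]:
        """circRNAs directly associated with *disease*."""
        return frozenset(c for c, d in self.pairs if d == disease)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ExpressionProfileSet:
    """circRNA × condition expression matrix for one source.

    ``mask`` marks missing cells (True = missing); values under the mask are
    NaN and must be excluded pairwise from any correlation.
    """

    source: str
    circ_ids: list[str]
    conditions: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.circ_ids), len(self.conditions)):
            raise PrecdaError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.circ_ids)} circRNAs x {len(self.conditions)} conditions"
            )
        if len(set(self.conditions)) != len(self.conditions):
            raise PrecdaError("condition names must be unique")
        if len(set(self.circ_ids)) != len(self.circ_ids):
            raise PrecdaError("circRNA row IDs must be unique")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise PrecdaError("missing-value mask shape mismatch")

    def profile(self, circ: str) -> np.ndarray:
        row = self.values[self.circ_ids.index(circ)].copy()
        row[self.mask[self.circ_ids.index(circ)]] = np.nan
        return row


@dataclass
class DiseaseSimilarityMatrix:
    """Symmetric disease × disease similarity matrix in [0, 1], unit diagonal.

    Produced upstream by an ontology-aware disease-similarity method and
    consumed here as an opaque input.
    """

    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.disease_ids)
        if self.values.shape != (n, n):
            raise PrecdaError("disease similarity matrix must be square over disease_ids")
        if len(set(self.disease_ids)) != n:
            raise PrecdaError("duplicate disease IDs in similarity matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise PrecdaError("disease similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise PrecdaError("disease similarity matrix diagonal must be 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise PrecdaError("disease similarity entries must lie in [0, 1]")
        self._index = {d: i for i, d in enumerate(self.disease_ids)}

    def __contains__(self, disease: str) -> bool:
        return disease in self._index

    def loc(self, dis_a: str, dis_b: str) -> float:
        try:
            return float(self.values[self._index[dis_a], self._index[dis_b]])
        except KeyError as exc:
            raise PrecdaError(f"disease {exc.args[0]!r} absent from similarity matrix")

    def row(self, disease: str) -> np.ndarray:
        if disease not in self._index:
            raise PrecdaError(f"disease {disease!r} absent from similarity matrix")
        return self.values[self._index[disease]]


@dataclass(frozen=True)
class RejectedRow:
    """An input row that failed identifier harmonisation."""

    line: int
    circ_alias: str
    disease_alias: str
    reason: str


# ---------------------------------------------------------------------------
# readers / writers


def read_association_table(
    path: str | Path,
    synonym_map: SynonymMap | None = None,
    disease_map: SynonymMap | None = None,
    label: str | None = None,
    header: bool = False,
) -> tuple[AssociationDB, list[RejectedRow]]:
    """Read a TSV of (circRNA alias, disease alias[, source]) rows.

    Every row is routed through both synonym maps; rows whose circRNA or
    disease alias cannot be resolved are returned in the rejects report.
    Duplicate pairs collapse to one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    synonym_map = synonym_map or SynonymMap()
    disease_map = disease_map or SynonymMap()

    pairs: set[tuple[str, str]] = set()
    rejects: list[RejectedRow] = []
    first = header
    for lineno, line in _data_lines(path):
        if first:
            first = False
            continue
        cells = line.split("\t")
        if len(cells) < 2:
            raise ParseError(
                f"expected >=2 tab-separated columns, got {len(cells)}", line=lineno
            )
        circ_alias, dis_alias = cells[0].strip(), cells[1].strip()
        circ = synonym_map.resolve(circ_alias)
        dis = disease_map.resolve(dis_alias)
        if circ is None or dis is None:
            which = []
            if circ is None:
                which.append("circRNA")
            if dis is None:
                which.append("disease")
            rejects.append(
                RejectedRow(lineno, circ_alias, dis_alias, f"unmappable {' and '.join(which)} alias")
            )
            continue
        pairs.add((circ, dis))
    return AssociationDB(label=label or path.stem, pairs=frozenset(pairs)), rejects


def write_association_table(db: AssociationDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for circ, dis in sorted(db.pairs):
            fh.write(f"{circ}\t{dis}\t{db.label}\n")


def read_expression_matrix(path: str | Path, source_label: str) -> ExpressionProfileSet:
    """Read a TSV expression matrix: header of condition names, circRNA rows.

    Empty or NA-like cells are recorded in the missing mask; any other
    non-numeric cell raises :class:`ParseError` with its row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = list(_data_lines(path))
    if not lines:
        raise ParseError("empty expression matrix", line=1)
    header_no, header = lines[0]
    conditions = [c.strip() for c in header.split("\t")]
    if conditions and conditions[0] in {"", "circrna_id", "id"}:
        conditions = conditions[1:]
    circ_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(conditions) + 1:
            raise ParseError(
                f"expected {len(conditions) + 1} columns, got {len(cells)}", line=lineno
            )
        circ = cells[0].strip()
        if circ in circ_ids:
            raise ParseError(f"duplicate circRNA row ID {circ!r}", line=lineno)
        row = []
        for col, cell in enumerate(cells[1:], start=2):
            token = cell.strip()
            if token in _NA_TOKENS:
                row.append(np.nan)
                continue
            try:
                row.append(float(token))
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {token!r}", line=lineno, column=col
                ) from None
        circ_ids.append(circ)
        rows.append(row)
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(conditions)))
    return ExpressionProfileSet(
        source=source_label, circ_ids=circ_ids, conditions=conditions, values=values
    )


def write_expression_matrix(profiles: ExpressionProfileSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("circrna_id\t" + "\t".join(profiles.conditions) + "\n")
        for i, circ in enumerate(profiles.circ_ids):
            cells = [
                "NA" if profiles.mask[i, j] else repr(float(profiles.values[i, j]))
                for j in range(len(profiles.conditions))
            ]
            fh.write(circ + "\t" + "\t".join(cells) + "\n")


def read_disease_similarity(path: str | Path) -> DiseaseSimilarityMatrix:
    """Read a square TSV similarity matrix with disease-ID header row/column."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if list(df.index) != list(df.columns):
        raise ParseError("disease similarity header row and column disagree")
    return DiseaseSimilarityMatrix(
        disease_ids=[str(d) for d in df.index], values=df.to_numpy(dtype=float)
    )


def write_disease_similarity(dsim: DiseaseSimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(dsim.values, index=dsim.disease_ids, columns=dsim.disease_ids).to_csv(
        path, sep="\t"
    )


def read_ontology(path: str | Path) -> list[DiseaseTerm]:
    """Read disease terms from an OBO file or a flat TSV.

    The flat dialect is ``ontology_id <TAB> name <TAB> synonym|synonym|...``
    (synonyms column optional). OBO files are detected by extension or a
    ``format-version:`` first line and parsed with obonet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    is_obo = path.suffix.lower() == ".obo"
    if not is_obo:
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        is_obo = first.startswith("format-version:") or first.startswith("[Term]")
    if is_obo:
        return _read_obo(path)
    terms = []
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if len(cells) < 2:
            raise ParseError("expected >=2 columns (id, name[, synonyms])", line=lineno)
        synonyms = tuple(s for s in cells[2].split("|") if s) if len(cells) > 2 else ()
        xrefs = tuple(x for x in cells[3].split("|") if x) if len(cells) > 3 else ()
        terms.append(DiseaseTerm(cells[0].strip(), cells[1].strip(), synonyms, xrefs))
    return terms


def _read_obo(path: Path) -> list[DiseaseTerm]:
    import obonet

    graph = obonet.read_obo(str(path))
    terms = []
    for node, data in graph.nodes(data=True):
        synonyms = tuple(
            s.split('"')[1] for s in data.get("synonym", ()) if s.count('"') >= 2
        )
        terms.append(
            DiseaseTerm(
                ontology_id=node,
                name=data.get("name", node),
                synonyms=synonyms,
                xrefs=tuple(data.get("xref", ())),
            )
        )
    return terms


# ---------------------------------------------------------------------------
# harmonisation


def match_disease_names(
    names: Sequence[str], ontology: Sequence[DiseaseTerm]
) -> tuple[SynonymMap, list[str]]:
    """Map free-text disease names onto ontology IDs by exact string match.

    Matching is case-insensitive against each term's preferred name and all
    its synonyms; no fuzzy matching. Returns the map plus the list of names
    that matched nothing. Two terms claiming the same (case-folded) synonym
    raise :class:`AmbiguousSynonymError` naming both.
    """
    lookup: dict[str, str] = {}
    for term in ontology:
        for variant in (term.name, *term.synonyms):
            key = variant.casefold().strip()
            if not key:
                continue
            other = lookup.get(key)
            if other is not None and other != term.ontology_id:
                raise AmbiguousSynonymError(
                    f"synonym {variant!r} claimed by both {other} and {term.ontology_id}"
                )
            lookup[key] = term.ontology_id
    mapping = SynonymMap()
    unmatched: list[str] = []
    for name in names:
        hit = lookup.get(name.casefold().strip())
        if hit is None:
            unmatched.append(name)
        else:
            mapping.add(name, hit)
    return mapping, unmatched


def merge_synonyms_by_xref(terms: Sequence[DiseaseTerm]) -> list[DiseaseTerm]:
    """Union synonym lists across terms sharing an external-reference key.

    Emulates folding a second vocabulary's names into the ontology: any two
    terms citing the same xref pool their synonyms.
    """
    by_xref: dict[str, list[int]] = {}
    for i, term in enumerate(terms):
        for xref in term.xrefs:
            by_xref.setdefault(xref, []).append(i)
    extra: dict[int, set[str]] = {i: set() for i in range(len(terms))}
    for members in by_xref.values():
        pooled = set()
        for i in members:
            pooled.update(terms[i].synonyms)
            pooled.add(terms[i].name)
        for i in members:
            extra[i].update(pooled - {terms[i].name})
    return [
        DiseaseTerm(
            t.ontology_id,
            t.name,
            tuple(sorted(set(t.synonyms) | extra[i])),
            t.xrefs,
        )
        for i, t in enumerate(terms)
    ]


def intersect_databases(dbs: Sequence[AssociationDB]) -> pd.DataFrame:
    """Per-pair-of-sources counts of shared circRNAs, diseases and pairs."""
    if len(dbs) < 2:
        raise PrecdaError("need at least two databases to intersect")
    rows = []
    for i in range(len(dbs)):
        for j in range(i + 1, len(dbs)):
            a, b = dbs[i], dbs[j]
            rows.append(
                {
                    "source_a": a.label,
                    "source_b": b.label,
                    "shared_circrnas": len(a.circ_ids & b.circ_ids),
                    "shared_diseases": len(a.disease_ids & b.disease_ids),
                    "shared_pairs": len(a.pairs & b.pairs),
                }
            )
    return pd.DataFrame(rows)
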