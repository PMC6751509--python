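import numpy as np
import pytest

from precda.errors import AmbiguousSynonymError, ParseError, PrecdaError
from precda.ingest import (
    AssociationDB,
    DiseaseSimilarityMatrix,
    DiseaseTerm,
    SynonymMap,
    intersect_databases,
    match_disease_names,
    merge_synonyms_by_xref,
    read_association_table,
    read_disease_similarity,
    read_expression_matrix,
    read_ontology,
    write_association_table,
    write_disease_similarity,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestAssociationTable:
    def test_duplicate_pairs_collapse(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "c1\td1\nc2\td1\nc1\td1\n")
        db, rejects = read_association_table(p)
        assert len(db) == 2
        assert rejects == []

    def test_synonym_resolution_routes_alias_to_canonical(self, tmp_path):
        # CDR1as / ciRS-7 are the field's classic alias pair
        p = _write(tmp_path, "a.tsv", "ciRS-7\td1\n")
        smap = SynonymMap({"ciRS-7": "hsa_circ_0001946"})
        db, _ = read_association_table(p, synonym_map=smap)
        assert db.pairs == frozenset({("hsa_circ_0001946", "d1")})

    def test_unmappable_disease_goes_to_rejects_not_pairs(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "c1\tknown\nc1\tmystery\n")
        dmap = SynonymMap({"known": "DOID:1"})
        db, rejects = read_association_table(p, disease_map=dmap)
        assert db.pairs == frozenset({("c1", "DOID:1")})
        assert len(rejects) == 1
        assert rejects[0].disease_alias == "mystery"

    def test_accepted_plus_rejected_rows_account_for_all_input_rows(self, tmp_path):
        rows = ["c1\tDOID:1", "c2\tDOID:1", "c3\tbad", "c1\tDOID:1", "# comment"]
        p = _write(tmp_path, "a.tsv", "\n".join(rows) + "\n")
        dmap = SynonymMap({"DOID:1": "DOID:1"})
        db, rejects = read_association_table(p, disease_map=dmap)
        accepted_rows = 3  # includes the duplicate row
        assert accepted_rows + len(rejects) == 4  # data rows after comments
        assert len(db) == 2

    def test_malformed_row_names_line_number(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "c1\td1\nsingleton\n")
        with pytest.raises(ParseError, match="line 2"):
            read_association_table(p)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_association_table(tmp_path / "absent.tsv")

    def test_round_trip_preserves_pair_set(self, tmp_path, toy_assoc):
        out = tmp_path / "out.tsv"
        write_association_table(toy_assoc, out)
        back, _ = read_association_table(out, label="toy")
        assert back.pairs == toy_assoc.pairs


class TestSynonymMap:
    def test_canonical_ids_map_to_themselves(self):
        smap = SynonymMap({"alias": "canon"})
        assert smap.resolve("canon") == "canon"
        assert smap.resolve("alias") == "canon"

    def test_resolution_is_idempotent(self):
        smap = SynonymMap({"a": "x", "b": "y"})
        for alias in ("a", "b", "x", "y"):
            once = smap.resolve(alias)
            assert smap.resolve(once) == once

    def test_empty_map_is_identity(self):
        assert SynonymMap().resolve("anything") == "anything"

    def test_conflicting_alias_raises(self):
        smap = SynonymMap({"a": "x"})
        with pytest.raises(AmbiguousSynonymError):
            smap.add("a", "y")


class TestExpressionMatrix:
    def test_shape_and_labels(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "circrna_id\tt1\tt2\tt3\nc1\t1\t2\t3\nc2\t4\t5\t6\n")
        prof = read_expression_matrix(p, "src")
        assert prof.circ_ids == ["c1", "c2"]
        assert prof.conditions == ["t1", "t2", "t3"]
        assert prof.values.shape == (2, 3)

    def test_na_cell_sets_exactly_one_mask_entry(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "id\tt1\tt2\nc1\t1\tNA\nc2\t3\t4\n")
        prof = read_expression_matrix(p, "src")
        assert prof.mask.sum() == 1
        assert prof.mask[0, 1]

    def test_duplicate_row_ids_rejected(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "id\tt1\nc1\t1\nc1\t2\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_expression_matrix(p, "src")

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "id\tt1\tt2\nc1\t1\toops\n")
        with pytest.raises(ParseError, match="line 2, column 3"):
            read_expression_matrix(p, "src")


class TestDiseaseSimilarity:
    def test_round_trip(self, tmp_path, toy_dsim):
        out = tmp_path / "d.tsv"
        write_disease_similarity(toy_dsim, out)
        back = read_disease_similarity(out)
        assert back.disease_ids == toy_dsim.disease_ids
        np.testing.assert_allclose(back.values, toy_dsim.values)

    @pytest.mark.parametrize(
        "values, message",
        [
            (np.array([[1.0, 0.5], [0.4, 1.0]]), "symmetric"),
            (np.array([[0.9, 0.5], [0.5, 1.0]]), "diagonal"),
            (np.array([[1.0, 1.5], [1.5, 1.0]]), r"\[0, 1\]"),
        ],
    )
    def test_invalid_matrices_rejected(self, values, message):
        with pytest.raises(PrecdaError, match=message):
            DiseaseSimilarityMatrix(disease_ids=["a", "b"], values=values)


class TestDiseaseNameMatching:
    ONTOLOGY = [
        DiseaseTerm("DOID:3571", "liver cancer", ("hepatic cancer",)),
        DiseaseTerm("DOID:9351", "diabetes mellitus", ()),
    ]

    def test_case_insensitive_name_match(self):
        mapping, unmatched = match_disease_names(["Liver Cancer"], self.ONTOLOGY)
        assert mapping.resolve("Liver Cancer") == "DOID:3571"
        assert unmatched == []

    def test_synonym_only_match(self):
        mapping, _ = match_disease_names(["Hepatic Cancer"], self.ONTOLOGY)
        assert mapping.resolve("Hepatic Cancer") == "DOID:3571"

    def test_unmatched_name_reported_not_mapped(self):
        mapping, unmatched = match_disease_names(["gibberish"], self.ONTOLOGY)
        assert unmatched == ["gibberish"]
        assert "gibberish" not in mapping

    def test_shared_synonym_across_terms_is_ambiguous(self):
        ontology = [
            DiseaseTerm("DOID:1", "alpha", ("shared name",)),
            DiseaseTerm("DOID:2", "beta", ("Shared Name",)),
        ]
        with pytest.raises(AmbiguousSynonymError, match="DOID:1.*DOID:2"):
            match_disease_names(["alpha"], ontology)


class TestOntologyInputs:
    def test_flat_tsv_terms(self, tmp_path):
        p = tmp_path / "ont.tsv"
        p.write_text("DOID:1\tliver cancer\thepatic cancer|HCC\n", encoding="utf-8")
        terms = read_ontology(p)
        assert terms[0].ontology_id == "DOID:1"
        assert terms[0].synonyms == ("hepatic cancer", "HCC")

    def test_obo_terms(self, tmp_path):
        p = tmp_path / "ont.obo"
        p.write_text(
            "format-version: 1.2\n\n[Term]\nid: DOID:3571\nname: liver cancer\n"
            'synonym: "hepatic cancer" EXACT []\n',
            encoding="utf-8",
        )
        terms = read_ontology(p)
        assert terms == [
            DiseaseTerm("DOID:3571", "liver cancer", ("hepatic cancer",), ())
        ]

    def test_xref_merge_unions_synonyms(self):
        terms = [
            DiseaseTerm("DOID:1", "alpha", ("a1",), ("MESH:X",)),
            DiseaseTerm("MEDIC:9", "alpha-medic", ("a2",), ("MESH:X",)),
        ]
        merged = merge_synonyms_by_xref(terms)
        assert set(merged[0].synonyms) == {"a1", "a2", "alpha-medic"}
        assert set(merged[1].synonyms) == {"a1", "a2", "alpha"}


class TestIntersectDatabases:
    def test_identical_databases_share_everything(self, toy_assoc):
        table = intersect_databases([toy_assoc, toy_assoc])
        row = table.iloc[0]
        assert row["shared_circrnas"] == len(toy_assoc.circ_ids)
        assert row["shared_diseases"] == len(toy_assoc.disease_ids)
        assert row["shared_pairs"] == len(toy_assoc)

    def test_disjoint_databases_share_nothing(self):
        a = AssociationDB("A", frozenset({("c1", "d1")}))
        b = AssociationDB("B", frozenset({("c2", "d2")}))
        row = intersect_databases([a, b]).iloc[0]
        assert (row[["shared_circrnas", "shared_diseases", "shared_pairs"]] == 0).all()

    def test_partial_overlap_counts(self):
        # A={(c1,d1),(c2,d1)}, B={(c1,d1),(c1,d2)}: hand enumeration gives
        # shared circRNAs {c1}, shared diseases {d1}, shared pairs {(c1,d1)}
        a = AssociationDB("A", frozenset({("c1", "d1"), ("c2", "d1")}))
        b = AssociationDB("B", frozenset({("c1", "d1"), ("c1", "d2")}))
        row = intersect_databases([a, b]).iloc[0]
        assert row["shared_circrnas"] == 1
        assert row["shared_diseases"] == 1
        assert row["shared_pairs"] == 1
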