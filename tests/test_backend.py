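"""Fixture generator determinism and truth, store formats, query contract."""

import pandas as pd
import pytest

from patlink.backend import (
    BackendError,
    BackendTables,
    ConfigurationError,
    FixturePlan,
    TableBackend,
    compute_truth,
    generate_fixture,
    load_backend,
    read_tables_sqlite,
    read_tables_tsv,
    write_tables_sqlite,
    write_tables_tsv,
)
from patlink.model import PatentNumberError, parse_patent_number

from conftest import all_symbols, make_tables
from oracle import funnel_counts


class TestGeneratorDeterminism:
    def test_same_plan_same_seed_identical(self, forced_plan):
        t1, tr1 = generate_fixture(forced_plan)
        t2, tr2 = generate_fixture(forced_plan)
        assert t1.content_hash() == t2.content_hash()
        assert tr1.totals == tr2.totals and tr1.per_gene == tr2.per_gene

    def test_different_seed_differs(self, forced_plan):
        import dataclasses

        t1, _ = generate_fixture(forced_plan)
        t2, _ = generate_fixture(dataclasses.replace(forced_plan, seed=8))
        assert t1.content_hash() != t2.content_hash()

    def test_stream_isolation(self):
        """Changing the patent dimension must not perturb gene mapping draws."""
        import dataclasses

        base = FixturePlan(n_genes=30, seed=5)
        t1, _ = generate_fixture(base)
        t2, _ = generate_fixture(dataclasses.replace(base, patents_per_compound=(5, 5)))
        pd.testing.assert_frame_equal(t1.gene_xref, t2.gene_xref)
        pd.testing.assert_frame_equal(t1.activity, t2.activity)


class TestPlantedTruth:
    def test_closed_form_all_probabilities_one(self, forced_plan):
        tables, truth = generate_fixture(forced_plan)
        assert truth.totals["n_genes_mapped"] == 5
        assert truth.totals["n_modulators_validated"] == 5 * 3
        assert truth.totals["n_modulators_mappable"] == 5 * 3
        # serials are drawn without replacement, so no silent collisions
        assert truth.totals["n_patents_whitelisted_unique"] == 5 * 3 * 4

    def test_unmapped_genes_produce_nothing(self):
        plan = FixturePlan(n_genes=6, frac_gene_mapped=0.0, seed=1)
        tables, truth = generate_fixture(plan)
        assert truth.totals["n_modulators_validated"] == 0
        assert truth.totals["n_patents_whitelisted_unique"] == 0
        assert all(
            counts["n_modulators_validated"] == 0 for counts in truth.per_gene.values()
        )

    def test_truth_equals_independent_join_oracle(self, mixed_fixture):
        plan, tables, truth, _ = mixed_fixture
        expected = funnel_counts(tables, all_symbols(plan.n_genes))
        assert truth.totals == expected

    def test_planted_patent_numbers_are_grammar_valid(self, mixed_fixture):
        _, tables, _, _ = mixed_fixture
        for row in tables.patent_occurrence.itertuples(index=False):
            parse_patent_number(f"{row.authority}-{row.serial}-{row.kind}")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"frac_gene_mapped": 1.5},
            {"frac_compound_mapped": -0.1},
            {"modulators_per_gene": (5, 2)},
            {"year_range": (2021, 2000)},
            {"jurisdiction_weights": {}},
        ],
    )
    def test_invalid_plan_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            FixturePlan(**kwargs).validate()


class TestStores:
    def test_tsv_roundtrip(self, mixed_fixture, tmp_path):
        _, tables, _, _ = mixed_fixture
        write_tables_tsv(tables, tmp_path)
        back = read_tables_tsv(tmp_path)
        assert back.content_hash() == tables.content_hash()

    def test_sqlite_roundtrip(self, mixed_fixture, tmp_path):
        _, tables, _, _ = mixed_fixture
        path = tmp_path / "store.sqlite"
        write_tables_sqlite(tables, path)
        back = read_tables_sqlite(path)
        assert back.content_hash() == tables.content_hash()

    def test_load_backend_autodetects(self, mixed_fixture, tmp_path):
        _, tables, _, _ = mixed_fixture
        write_tables_tsv(tables, tmp_path / "dir")
        write_tables_sqlite(tables, tmp_path / "store.sqlite")
        b1 = load_backend(tmp_path / "dir")
        b2 = load_backend(tmp_path / "store.sqlite")
        assert b1.tables.content_hash() == b2.tables.content_hash()

    def test_missing_path_is_backend_error(self, tmp_path):
        with pytest.raises(BackendError):
            load_backend(tmp_path / "nope")

    def test_missing_table_file_is_backend_error(self, tmp_path):
        (tmp_path / "gene_xref.tsv").write_text("symbol\tuniprot_id\tchembl_target_id\n")
        with pytest.raises(BackendError):
            read_tables_tsv(tmp_path)


class TestQueryContract:
    def test_absent_is_not_an_error(self, tiny_backend):
        assert tiny_backend.query_gene_xref("NOSUCHGENE") == []
        assert tiny_backend.query_activities("CHEMBLT9999") == []
        assert tiny_backend.query_compound_xref("CHEMBL9999") is None
        assert tiny_backend.query_patents("SCHEMBL999") == []

    def test_planted_activity_rows_returned_exactly(self, tiny_tables, tiny_backend):
        rows = tiny_backend.query_activities("CHEMBLT0001")
        scan = tiny_tables.activity[tiny_tables.activity["target_id"] == "CHEMBLT0001"]
        assert len(rows) == len(scan)
        assert {r.compound_id for r in rows} == set(scan["compound_id"])

    def test_patents_come_back_parsed(self, tiny_backend):
        docs = tiny_backend.query_patents("SCHEMBL001")
        assert {d.number for d in docs} == {
            "US-8123456-B2", "WO-2015123456-A1", "EP-1234567-A1",
        }
        assert all(d.publication_date is not None for d in docs)

    def test_malformed_planted_serial_surfaces_with_provenance(self, tiny_tables):
        bad = tiny_tables.patent_occurrence.copy()
        bad.loc[0, "serial"] = "12345"  # below the 7-digit minimum
        tables = BackendTables(
            gene_xref=tiny_tables.gene_xref,
            activity=tiny_tables.activity,
            compound_xref=tiny_tables.compound_xref,
            patent_occurrence=bad,
        )
        with pytest.raises(PatentNumberError, match="SCHEMBL001"):
            TableBackend(tables)

    def test_duplicate_primary_key_rejected(self, tiny_tables):
        dup = pd.concat([tiny_tables.gene_xref, tiny_tables.gene_xref.iloc[:1]])
        with pytest.raises(BackendError, match="gene_xref"):
            TableBackend(
                BackendTables(
                    gene_xref=dup.reset_index(drop=True),
                    activity=tiny_tables.activity,
                    compound_xref=tiny_tables.compound_xref,
                    patent_occurrence=tiny_tables.patent_occurrence,
                )
            )


def test_compute_truth_respects_filters(tiny_tables):
    """Only B/F-evidenced, xref-mapped, whitelisted chains count."""
    truth = compute_truth(tiny_tables)
    # FGFR3: CHEMBL0001 (B+F, mappable, 2 whitelisted patents of 3),
    # CHEMBL0002 (B but unmappable), CHEMBL0003 is ADMET-only.
    assert truth.per_gene["FGFR3"] == {
        "n_modulators_validated": 2,
        "n_modulators_mappable": 1,
        "n_modulators_with_patents": 1,
        "n_patents_whitelisted_unique": 2,
    }
    # KRT14's only evidence row is tox-type
    assert truth.per_gene["KRT14"]["n_modulators_validated"] == 0
    assert truth.totals["n_genes_mapped"] == 2
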