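"""Landscape analytics: assignee rules, partition laws, timelines."""

import random
from datetime import date

import pytest

from patlink.landscape import (
    AssigneeRules,
    classify_assignee,
    gene_timeline,
    summarize,
)
from patlink.model import GenePatentLink, PatentDocument, parse_patent_number
from patlink.pipeline import run_pipeline

from conftest import all_symbols
from oracle import doc_whitelisted, groupby_counts


def _link(gene, number, codes=("C07D 1/00",), pub=None, assignees=("JANE DOE",)):
    return GenePatentLink(
        gene=gene,
        uniprot_id="P00001",
        chembl_target_id="CHEMBLT0001",
        modulator_chembl_id="CHEMBL000001",
        modulator_surechembl_id="SCHEMBL000001",
        patent=PatentDocument(
            identifier=parse_patent_number(number),
            classification_codes=frozenset(codes),
            publication_date=pub,
            assignees=tuple(assignees),
        ),
    )


class TestClassifyAssignee:
    @pytest.mark.parametrize(
        "names, expected",
        [
            (["Novartis Pharma AG"], "industry"),
            (["University of Bonn"], "academic"),
            (["Jane Doe", "Acme Therapeutics Inc"], "industry"),  # precedence
            (["Jane Doe", "Karolinska Institute"], "academic"),
            (["Jane Doe"], "individual"),
            ([], "individual"),
        ],
    )
    def test_categories(self, names, expected):
        assert classify_assignee(names, AssigneeRules()) == expected

    def test_word_boundary_matching(self):
        # "AGILE" must not match the keyword "AG"
        assert classify_assignee(["AGILE PARTNERS"], AssigneeRules()) == "individual"

    def test_precedence_matches_all_pairs_scan(self):
        """Cross-check against a naive keyword scan over every (name, kw) pair."""
        import re

        rules = AssigneeRules()
        rng = random.Random(5)
        pool = [
            "ACME THERAPEUTICS INC", "UNIVERSITY OF X", "JANE DOE",
            "BIG PHARMA LLC", "STATE INSTITUTE", "WEI ZHANG", "FOO HOSPITAL",
        ]
        for _ in range(200):
            names = rng.sample(pool, rng.randint(0, 3))
            hit_ind = any(
                re.search(rf"\b{kw}\b", n.upper())
                for n in names
                for kw in rules.industry_keywords
            )
            hit_acad = any(
                re.search(rf"\b{kw}\b", n.upper())
                for n in names
                for kw in rules.academic_keywords
            )
            expected = "industry" if hit_ind else "academic" if hit_acad else "individual"
            assert classify_assignee(names, rules) == expected

    def test_overlapping_keyword_lists_rejected(self):
        with pytest.raises(ValueError):
            AssigneeRules(industry_keywords=("INC", "UNIV"), academic_keywords=("UNIV",))


class TestSummarize:
    def test_dedup_before_tallying(self):
        links = [
            _link("G1", "US-1234567-A1"),
            _link("G2", "US-1234567-A1"),
            _link("G1", "EP-7654321-B1"),
        ]
        s = summarize(links)
        assert s.n_unique_patents == 2
        assert s.by_jurisdiction == {"US": 1, "EP": 1}
        assert s.by_grant_status == {"application": 1, "granted": 1}

    def test_multilabel_classification_counts(self):
        links = [_link("G1", "US-1234567-A1", codes=("C07D 401/04", "C07K 16/00"))]
        s = summarize(links)
        assert s.by_class_subclass == {"C07D": 1, "C07K": 1}
        assert sum(s.by_class_subclass.values()) > s.n_unique_patents

    def test_null_dates_under_unknown_sentinel(self):
        links = [
            _link("G1", "US-1234567-A1", pub=None),
            _link("G1", "EP-7654321-A1", pub=date(2010, 5, 1)),
        ]
        s = summarize(links)
        assert s.by_year == {"unknown": 1, "2010": 1}

    def test_partition_laws_on_fixture_run(self, mixed_fixture):
        plan, _, _, backend = mixed_fixture
        result = run_pipeline(all_symbols(plan.n_genes), backend)
        s = summarize(result.links)
        s.check_partition_laws()  # raises on violation
        assert s.n_unique_patents == result.funnel["n_patents_whitelisted_unique"]

    def test_invariant_under_link_permutation(self, mixed_fixture):
        plan, _, _, backend = mixed_fixture
        result = run_pipeline(all_symbols(plan.n_genes), backend)
        shuffled = list(result.links)
        random.Random(1).shuffle(shuffled)
        assert summarize(result.links).to_json() == summarize(shuffled).to_json()

    def test_tallies_equal_groupby_over_planted_table(self, mixed_fixture):
        """Counting oracle: direct group-by over the planted patent table
        restricted to whitelisted, linked documents."""
        plan, tables, _, backend = mixed_fixture
        result = run_pipeline(all_symbols(plan.n_genes), backend)
        s = summarize(result.links)

        linked_ids = {l.modulator_surechembl_id for l in result.links}
        rows = {}
        for r in tables.patent_occurrence.to_dict("records"):
            codes = [c for c in r["classification_codes"].split(";") if c]
            if r["surechembl_id"] in linked_ids and doc_whitelisted(
                codes, plan.whitelist_prefixes
            ):
                rows.setdefault((r["authority"], r["serial"], r["kind"]), r)
        docs = list(rows.values())
        assert s.n_unique_patents == len(docs)
        assert s.by_jurisdiction == groupby_counts(docs, lambda r: r["authority"])
        assert s.by_year == groupby_counts(docs, lambda r: r["publication_date"][:4])


class TestGeneTimeline:
    def test_dedup_then_count(self):
        links = [
            _link("G1", "US-1234567-A1", pub=date(2002, 1, 1)),
            _link("G1", "US-1234567-A1", pub=date(2002, 1, 1)),  # duplicate number
            _link("G1", "EP-7654321-A1", pub=date(2008, 1, 1)),
        ]
        assert gene_timeline(links, "G1") == {2002: 1, 2008: 1}

    def test_distinct_numbers_same_year_both_count(self):
        links = [
            _link("G1", "US-1234567-A1", pub=date(2002, 1, 1)),
            _link("G1", "US-7654321-A1", pub=date(2002, 1, 1)),
        ]
        assert gene_timeline(links, "G1") == {2002: 2}

    def test_unknown_gene_empty_mapping(self):
        assert gene_timeline([_link("G1", "US-1234567-A1")], "NOPE") == {}

    def test_per_gene_sums_dominate_global_by_year(self, mixed_fixture):
        """Genes can share patents, so per-gene counts can exceed global."""
        plan, _, _, backend = mixed_fixture
        result = run_pipeline(all_symbols(plan.n_genes), backend)
        s = summarize(result.links)
        per_gene_sum = {}
        for timeline in s.per_gene_timeline.values():
            for year, count in timeline.items():
                per_gene_sum[year] = per_gene_sum.get(year, 0) + count
        for year, total in s.by_year.items():
            if year == "unknown":
                continue
            assert per_gene_sum.get(year, 0) >= total

    def test_timeline_respects_fixture_year_range(self, mixed_fixture):
        plan, _, _, backend = mixed_fixture
        result = run_pipeline(all_symbols(plan.n_genes), backend)
        genes = {l.gene for l in result.links}
        lo, hi = plan.year_range
        for gene in genes:
            for year in gene_timeline(result.links, gene):
                assert lo <= year <= hi
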