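import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracle.py importable

from patlink.backend import BackendTables, FixturePlan, TableBackend, generate_fixture


def make_tables(gene_rows, act_rows, cmp_rows, pat_rows) -> BackendTables:
    """Hand-build a relational snapshot from plain tuples."""
    return BackendTables(
        gene_xref=pd.DataFrame(
            gene_rows, columns=["symbol", "uniprot_id", "chembl_target_id"]
        ).astype(str),
        activity=pd.DataFrame(
            act_rows,
            columns=["compound_id", "target_id", "assay_type", "action", "potency_value"],
        ).astype(str),
        compound_xref=pd.DataFrame(
            cmp_rows, columns=["chembl_id", "surechembl_id", "modality"]
        ).astype(str),
        patent_occurrence=pd.DataFrame(
            pat_rows,
            columns=[
                "surechembl_id", "authority", "serial", "kind",
                "classification_codes", "publication_date", "assignees",
            ],
        ).astype(str),
    )


@pytest.fixture
def tiny_tables() -> BackendTables:
    """A small hand-built graph with known attrition at every hop.

    FGFR3 is fully mapped with two compounds (one patent-mappable, one
    not); KRT14 maps to a target with no qualifying evidence; MECP2 lacks
    a target cross-reference; PLOD1 has no UniProt accession at all.
    """
    return make_tables(
        gene_rows=[
            ("FGFR3", "P22607", "CHEMBLT0001"),
            ("KRT14", "P02533", "CHEMBLT0002"),
            ("MECP2", "P51608", ""),
            ("PLOD1", "", ""),
        ],
        act_rows=[
            ("CHEMBL0001", "CHEMBLT0001", "B", "inhibition", "7.2"),
            ("CHEMBL0001", "CHEMBLT0001", "F", "inhibition", ""),
            ("CHEMBL0002", "CHEMBLT0001", "B", "activation", "6.0"),
            ("CHEMBL0003", "CHEMBLT0001", "A", "other", "5.0"),  # ADMET only
            ("CHEMBL0004", "CHEMBLT0002", "T", "unknown", ""),  # tox only
        ],
        cmp_rows=[
            ("CHEMBL0001", "SCHEMBL001", "small_molecule"),
            ("CHEMBL0002", "", "small_molecule"),
            ("CHEMBL0003", "SCHEMBL003", "biological"),
            ("CHEMBL0004", "SCHEMBL004", "small_molecule"),
        ],
        pat_rows=[
            ("SCHEMBL001", "US", "8123456", "B2", "C07D 401/04;A61P 35/00",
             "2008-03-15", "ACME THERAPEUTICS INC"),
            ("SCHEMBL001", "WO", "2015123456", "A1", "C07K 16/00",
             "2015-06-01", "UNIVERSITY OF BONN"),
            ("SCHEMBL001", "EP", "1234567", "A1", "G06F 17/00",  # off-whitelist
             "2002-01-20", "JANE DOE"),
            ("SCHEMBL003", "US", "20210012345", "A1", "C12Q 1/68",
             "2021-09-30", "JOHN SMITH"),
        ],
    )


@pytest.fixture
def tiny_backend(tiny_tables) -> TableBackend:
    return TableBackend(tiny_tables)


@pytest.fixture
def forced_plan() -> FixturePlan:
    """All probabilities 1: funnel counts follow closed-form products."""
    return FixturePlan(
        n_genes=5,
        frac_gene_mapped=1.0,
        modulators_per_gene=(3, 3),
        frac_evidence_allowed=1.0,
        frac_compound_mapped=1.0,
        patents_per_compound=(4, 4),
        frac_patent_whitelisted=1.0,
        seed=7,
    )


@pytest.fixture
def mixed_fixture():
    """A mid-size fixture with attrition at every hop, plus its backend."""
    plan = FixturePlan(
        n_genes=20,
        frac_gene_mapped=0.6,
        modulators_per_gene=(1, 8),
        frac_evidence_allowed=0.7,
        frac_compound_mapped=0.5,
        patents_per_compound=(0, 3),
        frac_patent_whitelisted=0.7,
        seed=123,
    )
    tables, truth = generate_fixture(plan)
    return plan, tables, truth, TableBackend(tables)


def all_symbols(n: int):
    return [f"GENE{i + 1:04d}" for i in range(n)]
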