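"""Stage 0: gene-symbol harmonization and prevalence-based gene selection.

User gene symbols are normalized (trim + uppercase; alias resolution is the
backend cross-reference table's job, not fuzzy matching here) and resolved
through two hops: symbol -> UniProt accession -> ChEMBL target identifier.
Unmapped symbols are reported and skipped, never fatal -- real landscapes
tolerate extensive attrition at this hop.

The module also selects an input gene list from a disease-gene table by
epidemiological prevalence, the entry point for disease-centric runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .backend import Backend
from .model import GeneRecord, MAPPED, NO_TARGET, NO_UNIPROT


class UsageError(ValueError):
    """Caller misuse (empty input list, malformed input file)."""


@dataclass
class HarmonizationReport:
    """Accounting of the harmonization hop: every input symbol is either
    mapped or listed in ``unmapped`` with the hop that failed."""

    n_input: int
    n_mapped: int
    unmapped: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        assert self.n_input == self.n_mapped + len(self.unmapped)


@dataclass(frozen=True)
class DiseaseGeneRow:
    """One disease-gene association with prevalence in cases per 100,000."""

    disease_id: str
    disease_name: str
    gene_symbol: str
    prevalence_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def harmonize_genes(
    symbols: Sequence[str], backend: Backend
) -> Tuple[List[GeneRecord], HarmonizationReport]:
    """Resolve symbols to (UniProt, ChEMBL target) records via the backend.

    Duplicates are collapsed case-insensitively, keeping first-occurrence
    order.  A symbol with several target cross-references yields one record
    per (symbol, target) pair; a symbol absent from the cross-reference
    table yields a single unmapped record.  The report counts distinct
    input symbols; a symbol counts as mapped if at least one of its records
    is fully mapped.
    """
    if not symbols:
        raise UsageError("gene symbol list is empty")
    seen = {}
    for raw in symbols:
        norm = normalize_symbol(raw)
        if norm and norm not in seen:
            seen[norm] = raw
    if not seen:
        raise UsageError("gene symbol list contains no non-blank symbols")

    records: List[GeneRecord] = []
    unmapped: List[Tuple[str, str]] = []
    n_mapped = 0
    for norm, raw in seen.items():
        rows = backend.query_gene_xref(norm)
        symbol_statuses = []
        if not rows:
            rec = GeneRecord(raw, norm, None, None, NO_UNIPROT)
            records.append(rec)
            symbol_statuses.append(NO_UNIPROT)
        else:
            for row in rows:
                if row.uniprot_id and row.chembl_target_id:
                    status = MAPPED
                elif row.uniprot_id:
                    status = NO_TARGET
                else:
                    status = NO_UNIPROT
                records.append(
                    GeneRecord(
                        raw,
                        norm,
                        row.uniprot_id if status != NO_UNIPROT else None,
                        row.chembl_target_id if status == MAPPED else None,
                        status,
                    )
                )
                symbol_statuses.append(status)
        if MAPPED in symbol_statuses:
            n_mapped += 1
        else:
            unmapped.append((norm, symbol_statuses[0]))
    report = HarmonizationReport(
        n_input=len(seen), n_mapped=n_mapped, unmapped=unmapped
    )
    return records, report


def select_genes_by_disease_prevalence(
    rows: Sequence[DiseaseGeneRow], min_prevalence: float
) -> Tuple[List[str], List[str]]:
    """Genes of diseases at or above a prevalence threshold.

    Diseases with prevalence below the threshold -- or with no recorded
    prevalence at all -- are dropped (the threshold is inclusive: exactly
    ``min_prevalence`` is retained).  Returns the distinct gene symbols of
    the retained diseases sorted lexicographically, and the retained
    disease ids in first-occurrence order.
    """
    if min_prevalence < 0:
        raise UsageError(f"min_prevalence must be >= 0, got {min_prevalence}")
    retained = [
        r
        for r in rows
        if r.prevalence_value is not None and r.prevalence_value >= min_prevalence
    ]
    genes = sorted({normalize_symbol(r.gene_symbol) for r in retained})
    diseases = list(dict.fromkeys(r.disease_id for r in retained))
    return genes, diseases


# --------------------------------------------------------------------------
# File formats


def read_gene_list(path) -> List[str]:
    """Plain-text gene list: one symbol per line, '#' comments and blanks ignored."""
    p = Path(path)
    if not p.exists():
        raise UsageError(f"gene list not found: {p}")
    symbols = []
    for line in p.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    if not symbols:
        raise UsageError(f"gene list {p} contains no symbols")
    return symbols


def read_disease_table(path) -> List[DiseaseGeneRow]:
    """Disease-gene TSV with header (disease_id, disease_name, gene_symbol,
    prevalence_per_100k); empty prevalence cells mean unknown."""
    p = Path(path)
    if not p.exists():
        raise UsageError(f"disease table not found: {p}")
    frame = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    required = {"disease_id", "disease_name", "gene_symbol", "prevalence_per_100k"}
    missing = required - set(frame.columns)
    if missing:
        raise UsageError(f"disease table {p} missing columns {sorted(missing)}")
    rows = []
    for t in frame.itertuples(index=False):
        prev = float(t.prevalence_per_100k) if t.prevalence_per_100k else None
        rows.append(DiseaseGeneRow(t.disease_id, t.disease_name, t.gene_symbol, prev))
    return rows


def report_to_frame(
    records: Sequence[GeneRecord], report: HarmonizationReport
) -> pd.DataFrame:
    """Long-format harmonization report for TSV output."""
    return pd.DataFrame(
        [
            {
                "input_symbol": r.input_symbol,
                "normalized_symbol": r.normalized_symbol,
                "uniprot_id": r.uniprot_id or "",
                "chembl_target_id": r.chembl_target_id or "",
                "mapping_status": r.mapping_status,
            }
            for r in records
        ]
    )
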