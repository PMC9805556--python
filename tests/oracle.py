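"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is implemented with plain-Python loops over raw table rows,
deliberately sharing no code with the package's pipeline, generator or
truth computation: the package imports nothing from this module and this
module imports nothing from the package's stage logic.
"""

from __future__ import annotations

import re
from typing import Dict, List, Sequence, Set, Tuple

# Reference grammar for the dash-separated patent number (authority, 7-11
# digit serial, kind letter + optional digit), case-insensitive on letters.
PATENT_NUMBER_RE = re.compile(
    r"\s*([A-Za-z]{2})\s*-\s*([0-9]{7,11})\s*-\s*([A-Za-z][0-9]?)\s*\Z"
)


def grammar_accepts(raw: str) -> bool:
    return bool(PATENT_NUMBER_RE.fullmatch(raw))


def _norm_code(code: str) -> str:
    return re.sub(r"\s+", "", code).upper()


def code_matches(code: str, entry: str) -> bool:
    return _norm_code(code).startswith(_norm_code(entry))


def doc_whitelisted(codes: Sequence[str], whitelist: Sequence[str]) -> bool:
    ok = False
    for code in codes:
        for entry in whitelist:
            if code_matches(code, entry):
                ok = True
    return ok


def evidence_passes(
    assay_type: str,
    potency_present: bool,
    action: str,
    allowed_assay_types: Set[str],
    require_potency: bool,
    allowed_actions,
) -> bool:
    """Truth-table reference for the evidence filter."""
    ok = assay_type in allowed_assay_types
    if require_potency and not potency_present:
        ok = False
    if allowed_actions != "any" and action not in allowed_actions:
        ok = False
    return ok


def _rows(frame) -> List[dict]:
    return frame.to_dict("records")


def triple_join_links(
    tables,
    symbols: Sequence[str],
    allowed_assay_types: Set[str] = frozenset({"B", "F"}),
    whitelist: Sequence[str] = ("A61K", "A61P", "C07", "C12", "C40B"),
) -> List[Tuple[str, str, str, str, str, str]]:
    """Naive three-way join with the stage filters applied.

    Returns sorted rows (gene, uniprot, target, chembl_id, surechembl_id,
    patent_number) -- one per (gene, modulator, unique patent) chain, the
    same granularity as the pipeline's links table.
    """
    wanted = []
    seen = set()
    for s in symbols:
        n = s.strip().upper()
        if n and n not in seen:
            seen.add(n)
            wanted.append(n)

    gene_rows = [r for r in _rows(tables.gene_xref) if r["symbol"] in seen]
    act_rows = _rows(tables.activity)
    cmp_rows = {r["chembl_id"]: r for r in _rows(tables.compound_xref)}
    pat_rows = _rows(tables.patent_occurrence)

    out = []
    for g in gene_rows:
        if not g["uniprot_id"] or not g["chembl_target_id"]:
            continue
        compounds = sorted(
            {
                a["compound_id"]
                for a in act_rows
                if a["target_id"] == g["chembl_target_id"]
                and a["assay_type"] in allowed_assay_types
            }
        )
        for cid in compounds:
            xref = cmp_rows.get(cid)
            if xref is None or not xref["surechembl_id"]:
                continue
            sid = xref["surechembl_id"]
            numbers = set()
            for p in pat_rows:
                if p["surechembl_id"] != sid:
                    continue
                codes = [c for c in str(p["classification_codes"]).split(";") if c]
                if doc_whitelisted(codes, whitelist):
                    numbers.add(f"{p['authority']}-{p['serial']}-{p['kind']}")
            for number in sorted(numbers):
                out.append(
                    (g["symbol"], g["uniprot_id"], g["chembl_target_id"], cid, sid, number)
                )
    return sorted(out)


def funnel_counts(
    tables,
    symbols: Sequence[str],
    allowed_assay_types: Set[str] = frozenset({"B", "F"}),
    whitelist: Sequence[str] = ("A61K", "A61P", "C07", "C12", "C40B"),
) -> Dict[str, int]:
    """Independent funnel tallies (same keys as truth.json totals)."""
    norm = list(dict.fromkeys(s.strip().upper() for s in symbols if s.strip()))
    gene_rows = {r["symbol"]: r for r in _rows(tables.gene_xref)}
    act_rows = _rows(tables.activity)
    cmp_rows = {r["chembl_id"]: r for r in _rows(tables.compound_xref)}
    pat_rows = _rows(tables.patent_occurrence)

    n_mapped = 0
    genes_with_mods = 0
    genes_with_patents = 0
    n_validated = 0
    n_mappable = 0
    n_with_patents = 0
    global_numbers = set()

    for s in norm:
        g = gene_rows.get(s)
        if g is None or not g["uniprot_id"] or not g["chembl_target_id"]:
            continue
        n_mapped += 1
        compounds = sorted(
            {
                a["compound_id"]
                for a in act_rows
                if a["target_id"] == g["chembl_target_id"]
                and a["assay_type"] in allowed_assay_types
            }
        )
        n_validated += len(compounds)
        if compounds:
            genes_with_mods += 1
        gene_numbers = set()
        for cid in compounds:
            xref = cmp_rows.get(cid)
            if xref is None or not xref["surechembl_id"]:
                continue
            n_mappable += 1
            numbers = set()
            for p in pat_rows:
                if p["surechembl_id"] != xref["surechembl_id"]:
                    continue
                codes = [c for c in str(p["classification_codes"]).split(";") if c]
                if doc_whitelisted(codes, whitelist):
                    numbers.add(f"{p['authority']}-{p['serial']}-{p['kind']}")
            if numbers:
                n_with_patents += 1
            gene_numbers |= numbers
        if gene_numbers:
            genes_with_patents += 1
        global_numbers |= gene_numbers

    return {
        "n_genes": len(norm),
        "n_genes_mapped": n_mapped,
        "n_genes_with_modulators": genes_with_mods,
        "n_genes_with_patents": genes_with_patents,
        "n_modulators_validated": n_validated,
        "n_modulators_mappable": n_mappable,
        "n_modulators_with_patents": n_with_patents,
        "n_patents_whitelisted_unique": len(global_numbers),
    }


def groupby_counts(rows: Sequence[dict], key) -> Dict[str, int]:
    """Plain group-by counter used as the landscape counting oracle."""
    out: Dict[str, int] = {}
    for r in rows:
        k = key(r)
        out[k] = out.get(k, 0) + 1
    return out
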