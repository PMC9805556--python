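"""Stage 2: patent retrieval, classification filtering, dedup, link assembly.

Each patent-mappable modulator is resolved to the patent documents that
reference its chemistry, a classification whitelist keeps only documents in
pharmaceutically/chemically relevant IPC-CPC classes, duplicates are
collapsed by the full printed patent number (authority + serial + kind:
two publication stages of one application are distinct documents), and the
surviving documents are assembled into provenance-complete gene-patent
links.  Attrition at every step is logged in drop records so a run's
funnel is auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .backend import Backend, DEFAULT_WHITELIST_PREFIXES
from .model import (
    GenePatentLink,
    GeneRecord,
    Modulator,
    PatentDocument,
    classification_matches,
    sort_documents,
)

_ENTRY_RE = re.compile(r"[A-Z]([0-9]{2}([A-Z])?)?\Z")


@dataclass(frozen=True)
class ClassificationWhitelist:
    """Ordered set of IPC/CPC prefixes a patent must match to be kept.

    Entries may sit at section ("C"), class ("C07") or subclass ("C07D")
    granularity.  The default covers drug formulations and therapeutic
    activity (A61K, A61P), organic chemistry (C07), biochemistry (C12) and
    combinatorial chemistry (C40B).
    """

    entries: Tuple[str, ...] = DEFAULT_WHITELIST_PREFIXES

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("classification whitelist must be non-empty")
        for e in self.entries:
            if not _ENTRY_RE.fullmatch(e):
                raise ValueError(
                    f"whitelist entry {e!r} is not section/class/subclass "
                    "(letter, optional two digits, optional letter)"
                )


@dataclass(frozen=True)
class DropRecord:
    """One entity removed at a pipeline hop, with the reason."""

    stage: str
    entity_id: str
    reason: str


def passes_class_filter(doc: PatentDocument, wl: ClassificationWhitelist) -> bool:
    """True iff any code on the document matches any whitelist entry."""
    return any(
        classification_matches(code, entry)
        for code in doc.classification_codes
        for entry in wl.entries
    )


def extract_patents(
    mod: Modulator,
    backend: Backend,
    wl: ClassificationWhitelist = ClassificationWhitelist(),
    drops: Optional[List[DropRecord]] = None,
) -> List[PatentDocument]:
    """Whitelisted patent documents for one mappable modulator.

    Documents failing the class filter are recorded in ``drops`` (when
    given) so the per-modulator attrition is auditable.  A modulator with
    no documents at all yields an empty list -- absence is not an error.
    """
    if mod.surechembl_id is None:
        raise ValueError(
            f"extract_patents requires a patent-mappable modulator; "
            f"{mod.chembl_id} has no surechembl_id"
        )
    kept: List[PatentDocument] = []
    for doc in backend.query_patents(mod.surechembl_id):
        if passes_class_filter(doc, wl):
            kept.append(doc)
        elif drops is not None:
            drops.append(
                DropRecord(
                    stage="class_filter",
                    entity_id=f"{mod.chembl_id}:{doc.number}",
                    reason="no classification code matches the whitelist",
                )
            )
    return sort_documents(kept)


def dedupe_patents(docs: Sequence[PatentDocument]) -> List[PatentDocument]:
    """Unique documents by full patent number; first occurrence wins.

    Idempotent; output sorted by canonical number.
    """
    seen: Dict[Tuple[str, str, str], PatentDocument] = {}
    for doc in docs:
        seen.setdefault(doc.key, doc)
    return sort_documents(seen.values())


def build_links(
    gene: GeneRecord,
    mods: Sequence[Modulator],
    per_mod_patents: Mapping[str, Sequence[PatentDocument]],
) -> List[GenePatentLink]:
    """Assemble one link per (gene, modulator, unique patent) triple.

    A patent reached via k modulators of the gene yields k link rows (the
    provenance chains are distinct) but still counts once in unique-patent
    tallies, which deduplicate by patent number downstream.
    """
    links: List[GenePatentLink] = []
    for mod in mods:
        if mod.surechembl_id is None:
            continue
        for doc in dedupe_patents(per_mod_patents.get(mod.chembl_id, [])):
            links.append(
                GenePatentLink(
                    gene=gene.normalized_symbol,
                    uniprot_id=gene.uniprot_id,
                    chembl_target_id=gene.chembl_target_id,
                    modulator_chembl_id=mod.chembl_id,
                    modulator_surechembl_id=mod.surechembl_id,
                    patent=doc,
                )
            )
    return links


def links_to_frame(links: Sequence[GenePatentLink]) -> pd.DataFrame:
    columns = [
        "gene",
        "uniprot_id",
        "chembl_target_id",
        "chembl_id",
        "surechembl_id",
        "patent_number",
        "kind",
        "publication_date",
        "classification_codes",
        "assignees",
    ]
    rows = [
        {
            "gene": l.gene,
            "uniprot_id": l.uniprot_id,
            "chembl_target_id": l.chembl_target_id,
            "chembl_id": l.modulator_chembl_id,
            "surechembl_id": l.modulator_surechembl_id,
            "patent_number": l.patent.number,
            "kind": l.patent.identifier.kind,
            "publication_date": (
                l.patent.publication_date.isoformat() if l.patent.publication_date else ""
            ),
            "classification_codes": ";".join(sorted(l.patent.classification_codes)),
            "assignees": ";".join(l.patent.assignees),
        }
        for l in links
    ]
    return pd.DataFrame(rows, columns=columns)


def frame_to_links(frame: pd.DataFrame) -> List[GenePatentLink]:
    """Parse a links table back into link objects (for landscape runs)."""
    from datetime import date as _date

    from .model import parse_patent_number

    links = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            identifier = parse_patent_number(str(row.patent_number))
            pub = str(row.publication_date)
            doc = PatentDocument(
                identifier=identifier,
                classification_codes=frozenset(
                    c for c in str(row.classification_codes).split(";") if c
                ),
                publication_date=_date.fromisoformat(pub) if pub else None,
                assignees=tuple(a for a in str(row.assignees).split(";") if a),
            )
            links.append(
                GenePatentLink(
                    gene=str(row.gene),
                    uniprot_id=str(row.uniprot_id),
                    chembl_target_id=str(row.chembl_target_id),
                    modulator_chembl_id=str(row.chembl_id),
                    modulator_surechembl_id=str(row.surechembl_id),
                    patent=doc,
                )
            )
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"links table row {i} is malformed: {exc}") from exc
    return links


def drops_to_frame(drops: Sequence[DropRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"stage": d.stage, "entity_id": d.entity_id, "reason": d.reason} for d in drops],
        columns=["stage", "entity_id", "reason"],
    )
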