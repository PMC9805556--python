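"""Domain model shared across the gene->modulator->patent pipeline.

The central objects mirror the entities the pipeline harmonizes and links:

* :class:`GeneRecord` -- a user gene symbol resolved to a UniProt accession
  and a ChEMBL target identifier.
* :class:`ActivityEvidence` / :class:`Modulator` -- an experimentally
  measured compound-target interaction and the compound it validates.
* :class:`PatentIdentifier` / :class:`PatentDocument` -- a patent number
  parsed into its authority / serial / kind components and the document
  metadata attached to it.
* :class:`GenePatentLink` -- one fully mapped provenance chain
  gene -> modulator -> patent, the pipeline's atomic output row.

The module also owns the patent-number grammar.  A patent number is the
dash-separated triple ``AUTHORITY-SERIAL-KIND`` where the authority is a
two-letter patent-office code (US, EP, WO, ...), the serial is a 7-11 digit
string (leading zeros significant), and the kind is a grant-status code of
one letter plus an optional digit (A1, B2, or a bare letter).  Two numbers
differing in any component, including the kind code, denote distinct
documents.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import date
from typing import FrozenSet, Iterable, Optional, Tuple

# --------------------------------------------------------------------------
# Mapping status / action / modality vocabularies (plain strings so they
# serialize to TSV without ceremony).

MAPPED = "mapped"
NO_UNIPROT = "no_uniprot"
NO_TARGET = "no_target"
MAPPING_STATUSES = (MAPPED, NO_UNIPROT, NO_TARGET)

ACTIONS = ("activation", "inhibition", "other", "unknown")
MODALITIES = ("small_molecule", "biological", "unknown")

#: Patent authorities that publish applications but never grant.  WIPO (WO)
#: is the canonical member: its B-kind documents are re-publications, not
#: grants.
DEFAULT_APPLICATION_ONLY: FrozenSet[str] = frozenset({"WO"})


# --------------------------------------------------------------------------
# Patent-number grammar

_AUTHORITY_RE = re.compile(r"[A-Z]{2}\Z")
_SERIAL_RE = re.compile(r"[0-9]{7,11}\Z")
_KIND_RE = re.compile(r"[A-Z][0-9]?\Z")


class PatentNumberError(ValueError):
    """A patent number violating the AUTHORITY-SERIAL-KIND grammar.

    ``component`` names the offending part (``"structure"``, ``"authority"``,
    ``"serial"`` or ``"kind"``) so callers can report precisely what was
    wrong with an upstream record.
    """

    def __init__(self, component: str, message: str):
        self.component = component
        super().__init__(f"invalid patent number ({component}): {message}")


@dataclass(frozen=True, order=True)
class PatentIdentifier:
    """Parsed patent number: 2-letter authority, 7-11 digit serial, kind code."""

    authority: str
    serial: str
    kind: str

    def __post_init__(self) -> None:
        if not _AUTHORITY_RE.fullmatch(self.authority):
            raise PatentNumberError(
                "authority", f"{self.authority!r} is not two uppercase letters"
            )
        if not _SERIAL_RE.fullmatch(self.serial):
            raise PatentNumberError(
                "serial", f"{self.serial!r} is not a 7-11 digit string"
            )
        if not _KIND_RE.fullmatch(self.kind):
            raise PatentNumberError(
                "kind", f"{self.kind!r} is not a letter plus optional digit"
            )

    def __str__(self) -> str:
        return format_patent_number(self)


def parse_patent_number(raw: str) -> PatentIdentifier:
    """Parse ``"WO-2015123456-A1"`` into its authority/serial/kind triple.

    Whitespace around the number or around the dashes is ignored; the
    authority and kind are case-normalized to uppercase.  The serial is kept
    verbatim (``"0123456"`` and ``"123456"+"0"`` are different serials).

    Raises
    ------
    PatentNumberError
        If the input does not split into exactly three dash-separated parts
        or any part violates the grammar; the error names the offending
        component.
    """
    if not raw or not raw.strip():
        raise PatentNumberError("structure", "empty patent number")
    parts = [p.strip() for p in raw.strip().split("-")]
    if len(parts) != 3:
        raise PatentNumberError(
            "structure",
            f"{raw!r} has {len(parts)} dash-separated parts, expected 3",
        )
    authority, serial, kind = parts[0].upper(), parts[1], parts[2].upper()
    return PatentIdentifier(authority=authority, serial=serial, kind=kind)


def format_patent_number(pid: PatentIdentifier) -> str:
    """Canonical dash-separated text; inverse of :func:`parse_patent_number`."""
    return f"{pid.authority}-{pid.serial}-{pid.kind}"


def is_granted(
    pid: PatentIdentifier,
    application_only: FrozenSet[str] = DEFAULT_APPLICATION_ONLY,
) -> bool:
    """Whether the document is a grant.

    True iff the kind letter is ``B`` and the authority actually grants
    patents.  Authorities in ``application_only`` (default ``{WO}``) publish
    applications only, so even a B-kind document from them is not counted as
    granted.
    """
    return pid.kind[0] == "B" and pid.authority not in application_only


# --------------------------------------------------------------------------
# IPC/CPC classification codes.  IPC and CPC share the hierarchical prefix
# structure (section letter, two-digit class, subclass letter) so a single
# prefix match serves both namespaces.


def normalize_classification(code: str) -> str:
    """Uppercase and strip all whitespace: ``"c07d 401/04"`` -> ``"C07D401/04"``."""
    return "".join(code.split()).upper()


def classification_matches(code: str, whitelist_entry: str) -> bool:
    """Prefix test at section ("C"), class ("C07") or subclass ("C07D") level.

    Both arguments are normalized (case- and whitespace-insensitive) before
    the comparison, so ``classification_matches("c07d401/04", "C07D")`` is
    true.  Matching is monotone in granularity: a code matching ``"C07D"``
    necessarily matches ``"C07"`` and ``"C"``.
    """
    if not code or not whitelist_entry:
        raise ValueError("classification code and whitelist entry must be non-empty")
    return normalize_classification(code).startswith(
        normalize_classification(whitelist_entry)
    )


def classification_subclass(code: str) -> str:
    """4-character subclass prefix of a code (``"C07D 401/04"`` -> ``"C07D"``)."""
    return normalize_classification(code)[:4]


# --------------------------------------------------------------------------
# Gene / evidence / modulator records


@dataclass(frozen=True)
class GeneRecord:
    """A gene symbol with its two-hop identifier mapping.

    ``mapping_status`` is ``mapped`` iff both the UniProt accession and the
    ChEMBL target identifier resolved; ``no_uniprot`` / ``no_target`` name
    the first hop that failed.
    """

    input_symbol: str
    normalized_symbol: str
    uniprot_id: Optional[str] = None
    chembl_target_id: Optional[str] = None
    mapping_status: str = NO_UNIPROT

    def __post_init__(self) -> None:
        if self.input_symbol and not self.normalized_symbol:
            raise ValueError("normalized_symbol empty for non-empty input_symbol")
        if self.mapping_status not in MAPPING_STATUSES:
            raise ValueError(f"unknown mapping_status {self.mapping_status!r}")
        both = self.uniprot_id is not None and self.chembl_target_id is not None
        if (self.mapping_status == MAPPED) != both:
            raise ValueError(
                "mapping_status 'mapped' requires both uniprot_id and "
                "chembl_target_id (and vice versa)"
            )


@dataclass(frozen=True)
class ActivityEvidence:
    """One compound-target bioassay measurement.

    ``assay_type`` is the single-letter evidence-class code (B = binding,
    F = functional; other codes pass through).  ``potency_value`` is on the
    negative-log-molar scale (pChEMBL-like) and may be absent.
    """

    compound_id: str
    target_id: str
    assay_type: str
    action: str = "unknown"
    potency_value: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.assay_type) != 1:
            raise ValueError(f"assay_type must be one character, got {self.assay_type!r}")
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.potency_value is not None:
            if not math.isfinite(self.potency_value) or self.potency_value < 0:
                raise ValueError(
                    f"potency_value must be finite and >= 0, got {self.potency_value!r}"
                )


@dataclass(frozen=True)
class Modulator:
    """A chemical/biological agent with qualifying evidence for one gene.

    ``surechembl_id`` is present iff the compound is patent-mappable (has a
    cross-reference into the patent-chemistry namespace).
    """

    chembl_id: str
    surechembl_id: Optional[str]
    modality: str
    evidence: Tuple[ActivityEvidence, ...]
    source_gene: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def patent_mappable(self) -> bool:
        return self.surechembl_id is not None


# --------------------------------------------------------------------------
# Patent documents and links


@dataclass(frozen=True)
class PatentDocument:
    """A patent with parsed identifier, classification codes and metadata."""

    identifier: PatentIdentifier
    classification_codes: FrozenSet[str] = frozenset()
    publication_date: Optional[date] = None
    assignees: Tuple[str, ...] = ()
    title: Optional[str] = None

    def __post_init__(self) -> None:
        if any(not c for c in self.classification_codes):
            raise ValueError("classification_codes entries must be non-empty")

    @property
    def key(self) -> Tuple[str, str, str]:
        """Uniqueness key: the full printed patent number (authority, serial, kind)."""
        i = self.identifier
        return (i.authority, i.serial, i.kind)

    @property
    def number(self) -> str:
        return format_patent_number(self.identifier)

    @property
    def year(self) -> Optional[int]:
        return self.publication_date.year if self.publication_date else None


@dataclass(frozen=True)
class GenePatentLink:
    """One provenance chain gene -> modulator -> patent.

    Links only exist for fully mapped chains, so every identifier field is
    non-null; the patent has already passed the classification whitelist.
    """

    gene: str
    uniprot_id: str
    chembl_target_id: str
    modulator_chembl_id: str
    modulator_surechembl_id: str
    patent: PatentDocument

    def __post_init__(self) -> None:
        for f in (
            self.gene,
            self.uniprot_id,
            self.chembl_target_id,
            self.modulator_chembl_id,
            self.modulator_surechembl_id,
        ):
            if not f:
                raise ValueError("GenePatentLink identifier fields must be non-null")


def sort_documents(docs: Iterable[PatentDocument]) -> list:
    """Sort documents by canonical patent number."""
    return sorted(docs, key=lambda d: d.number)
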