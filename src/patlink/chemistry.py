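"""Stage 1: extract experimentally validated modulators per gene.

For each harmonized gene, the backend's bioactivity table is filtered to
evidence of the configured assay classes (default: binding and functional,
the two classes that demonstrate direct experimental validation of a
compound against the gene product) and grouped into one modulator per
distinct compound.  A second pass partitions the modulators by whether
they cross-reference into the patent-chemistry namespace -- only those can
reach patents in stage 2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import FrozenSet, List, Sequence, Tuple, Union

import pandas as pd

from .backend import Backend
from .model import ActivityEvidence, GeneRecord, MAPPED, Modulator


@dataclass(frozen=True)
class EvidenceFilterConfig:
    """Which bioactivity rows count as validation.

    ``allowed_assay_types`` are the single-letter evidence-class codes
    (default binding + functional).  ``require_potency`` additionally
    demands a recorded potency value; ``allowed_actions`` can restrict to
    direct regulation (activation/inhibition).  Both extra gates default to
    off: the operative restriction is the assay class.
    """

    allowed_assay_types: FrozenSet[str] = frozenset({"B", "F"})
    require_potency: bool = False
    allowed_actions: Union[str, FrozenSet[str]] = "any"

    def __post_init__(self) -> None:
        if not self.allowed_assay_types:
            raise ValueError("allowed_assay_types must be non-empty")


def passes_evidence_filter(e: ActivityEvidence, cfg: EvidenceFilterConfig) -> bool:
    if e.assay_type not in cfg.allowed_assay_types:
        return False
    if cfg.require_potency and e.potency_value is None:
        return False
    if cfg.allowed_actions != "any" and e.action not in cfg.allowed_actions:
        return False
    return True


def extract_modulators(
    gene: GeneRecord, backend: Backend, cfg: EvidenceFilterConfig = EvidenceFilterConfig()
) -> List[Modulator]:
    """One modulator per distinct compound with >= 1 passing evidence row.

    All passing rows are attached (evidence merged across assays: the
    deduplication key is the compound alone, since patents are per-compound
    and per-assay duplicates would double-count downstream).  Compounds
    whose every row fails the filter are excluded.  Output sorted by
    compound id.
    """
    if gene.mapping_status != MAPPED:
        raise ValueError(
            f"extract_modulators requires a mapped gene; {gene.normalized_symbol} "
            f"has status {gene.mapping_status}"
        )
    by_compound = {}
    for ev in backend.query_activities(gene.chembl_target_id):
        if passes_evidence_filter(ev, cfg):
            by_compound.setdefault(ev.compound_id, []).append(ev)
    return [
        Modulator(
            chembl_id=cid,
            surechembl_id=None,
            modality="unknown",
            evidence=tuple(by_compound[cid]),
            source_gene=gene.normalized_symbol,
        )
        for cid in sorted(by_compound)
    ]


def attach_patent_chemistry_ids(
    mods: Sequence[Modulator], backend: Backend
) -> Tuple[List[Modulator], List[Modulator]]:
    """Partition modulators by patent-chemistry mappability.

    A modulator is mappable iff its compound cross-reference row carries a
    SureChEMBL-style identifier; mappable modulators are returned with the
    identifier (and modality) attached.  The partition is exhaustive and
    disjoint over the input.
    """
    mappable: List[Modulator] = []
    unmappable: List[Modulator] = []
    for mod in mods:
        xref = backend.query_compound_xref(mod.chembl_id)
        if xref is not None and xref.surechembl_id:
            mappable.append(
                replace(mod, surechembl_id=xref.surechembl_id, modality=xref.modality)
            )
        else:
            modality = xref.modality if xref is not None else mod.modality
            unmappable.append(replace(mod, modality=modality))
    return mappable, unmappable


def modulators_to_frame(mods: Sequence[Modulator], gene: GeneRecord) -> pd.DataFrame:
    """Stage-1 TSV rows; unmappable modulators carry an empty surechembl_id."""
    return pd.DataFrame(
        [
            {
                "gene": m.source_gene,
                "chembl_target_id": gene.chembl_target_id or "",
                "chembl_id": m.chembl_id,
                "surechembl_id": m.surechembl_id or "",
                "modality": m.modality,
                "n_evidence": len(m.evidence),
                "assay_types_seen": ";".join(sorted({e.assay_type for e in m.evidence})),
            }
            for m in mods
        ]
    )
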