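"""End-to-end orchestration: harmonize -> extract modulators -> attach
patent-chemistry ids -> retrieve patents -> assemble links, plus output
writing and the run manifest.

The manifest records the resolved configuration, the backend content hash
and the row count at every funnel stage, so two runs can be compared and a
run can be audited against a fixture's planted truth.  All tabular outputs
are written atomically (temp file + rename): a crashed run never leaves a
half-written table that could masquerade as a result.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .backend import Backend, TableBackend
from .chemistry import (
    EvidenceFilterConfig,
    attach_patent_chemistry_ids,
    extract_modulators,
)
from .harmonize import HarmonizationReport, harmonize_genes, report_to_frame
from .landscape import AssigneeRules
from .model import GenePatentLink, GeneRecord, MAPPED, Modulator, PatentDocument
from .patents import (
    ClassificationWhitelist,
    DropRecord,
    build_links,
    drops_to_frame,
    extract_patents,
    links_to_frame,
)

logger = logging.getLogger("patlink")

FUNNEL_KEYS = (
    "n_genes",
    "n_genes_mapped",
    "n_genes_with_modulators",
    "n_genes_with_patents",
    "n_modulators_validated",
    "n_modulators_mappable",
    "n_modulators_with_patents",
    "n_patents_whitelisted_unique",
    "n_links",
)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (embedded in the manifest)."""

    backend_path: str
    gene_list_path: Optional[str] = None
    disease_table_path: Optional[str] = None
    prevalence_threshold: float = 10.0
    evidence_filter: EvidenceFilterConfig = field(default_factory=EvidenceFilterConfig)
    whitelist: ClassificationWhitelist = field(default_factory=ClassificationWhitelist)
    assignee_rules: AssigneeRules = field(default_factory=AssigneeRules)
    output_dir: str = "out"
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.gene_list_path is None) == (self.disease_table_path is None):
            raise ValueError(
                "exactly one of gene_list_path / disease_table_path must be given"
            )

    def to_dict(self) -> dict:
        return {
            "backend_path": self.backend_path,
            "gene_list_path": self.gene_list_path,
            "disease_table_path": self.disease_table_path,
            "prevalence_threshold": self.prevalence_threshold,
            "evidence_filter": {
                "allowed_assay_types": sorted(self.evidence_filter.allowed_assay_types),
                "require_potency": self.evidence_filter.require_potency,
                "allowed_actions": (
                    "any"
                    if self.evidence_filter.allowed_actions == "any"
                    else sorted(self.evidence_filter.allowed_actions)
                ),
            },
            "whitelist": list(self.whitelist.entries),
            "assignee_rules": {
                "industry_keywords": list(self.assignee_rules.industry_keywords),
                "academic_keywords": list(self.assignee_rules.academic_keywords),
            },
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }


@dataclass
class PipelineResult:
    """Everything one run produced, before serialization."""

    records: List[GeneRecord]
    report: HarmonizationReport
    modulators: List[Tuple[GeneRecord, Modulator]]
    links: List[GenePatentLink]
    drops: List[DropRecord]
    funnel: Dict[str, int]


def run_pipeline(
    symbols: Sequence[str],
    backend: Backend,
    evidence_cfg: EvidenceFilterConfig = EvidenceFilterConfig(),
    whitelist: ClassificationWhitelist = ClassificationWhitelist(),
) -> PipelineResult:
    """Run both stages over a gene list and assemble the link table.

    Per-gene failures (unmapped symbols, modulator-less targets,
    patent-less modulators) are logged as drops and the run continues;
    attrition is expected, not exceptional.
    """
    records, report = harmonize_genes(symbols, backend)
    drops: List[DropRecord] = []
    all_mods: List[Tuple[GeneRecord, Modulator]] = []
    all_links: List[GenePatentLink] = []

    genes_with_mods = set()
    genes_with_patents = set()
    n_validated = 0
    n_mappable = 0
    n_with_patents = 0
    unique_patent_keys = set()

    for symbol, status in report.unmapped:
        drops.append(DropRecord("gene_mapping", symbol, f"mapping_status={status}"))

    for rec in records:
        if rec.mapping_status != MAPPED:
            continue
        mods = extract_modulators(rec, backend, evidence_cfg)
        if not mods:
            drops.append(
                DropRecord(
                    "chemical_extractor",
                    rec.normalized_symbol,
                    "no compound with qualifying evidence",
                )
            )
        else:
            genes_with_mods.add(rec.normalized_symbol)
        n_validated += len(mods)

        mappable, unmappable = attach_patent_chemistry_ids(mods, backend)
        n_mappable += len(mappable)
        for mod in unmappable:
            drops.append(
                DropRecord(
                    "patent_mappability",
                    mod.chembl_id,
                    "no patent-chemistry cross-reference",
                )
            )
        all_mods.extend((rec, m) for m in mappable + unmappable)

        per_mod: Dict[str, List[PatentDocument]] = {}
        for mod in mappable:
            docs = extract_patents(mod, backend, whitelist, drops)
            if docs:
                n_with_patents += 1
            else:
                drops.append(
                    DropRecord(
                        "patent_extractor",
                        mod.chembl_id,
                        "no whitelisted patent document",
                    )
                )
            per_mod[mod.chembl_id] = docs
        links = build_links(rec, mappable, per_mod)
        if links:
            genes_with_patents.add(rec.normalized_symbol)
            unique_patent_keys |= {l.patent.key for l in links}
        all_links.extend(links)
        logger.info(
            "gene %s: %d modulators, %d mappable, %d links",
            rec.normalized_symbol,
            len(mods),
            len(mappable),
            len(links),
        )

    funnel = {
        "n_genes": report.n_input,
        "n_genes_mapped": report.n_mapped,
        "n_genes_with_modulators": len(genes_with_mods),
        "n_genes_with_patents": len(genes_with_patents),
        "n_modulators_validated": n_validated,
        "n_modulators_mappable": n_mappable,
        "n_modulators_with_patents": n_with_patents,
        "n_patents_whitelisted_unique": len(unique_patent_keys),
        "n_links": len(all_links),
    }
    return PipelineResult(records, report, all_mods, all_links, drops, funnel)


# --------------------------------------------------------------------------
# Atomic output writing


def atomic_write_text(text: str, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_frame(frame: pd.DataFrame, path) -> None:
    atomic_write_text(frame.to_csv(sep="\t", index=False), path)


def write_run_outputs(
    result: PipelineResult,
    config: RunConfig,
    backend: Backend,
    out_dir,
) -> Dict[str, str]:
    """Write modulators.tsv, links.tsv, drops.tsv, harmonization report and
    run_manifest.json; returns the paths written."""
    from .chemistry import modulators_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mod_frames = []
    by_gene: Dict[str, List[Modulator]] = {}
    gene_of: Dict[str, GeneRecord] = {}
    for rec, mod in result.modulators:
        by_gene.setdefault(rec.normalized_symbol, []).append(mod)
        gene_of[rec.normalized_symbol] = rec
    for symbol in sorted(by_gene):
        mod_frames.append(
            modulators_to_frame(
                sorted(by_gene[symbol], key=lambda m: m.chembl_id), gene_of[symbol]
            )
        )
    mod_columns = [
        "gene", "chembl_target_id", "chembl_id", "surechembl_id",
        "modality", "n_evidence", "assay_types_seen",
    ]
    mod_frame = (
        pd.concat(mod_frames, ignore_index=True)
        if mod_frames
        else pd.DataFrame(columns=mod_columns)
    )

    paths = {}
    paths["modulators"] = str(out / "modulators.tsv")
    atomic_write_frame(mod_frame, paths["modulators"])
    paths["links"] = str(out / "links.tsv")
    atomic_write_frame(links_to_frame(result.links), paths["links"])
    paths["drops"] = str(out / "drops.tsv")
    atomic_write_frame(drops_to_frame(result.drops), paths["drops"])
    paths["harmonization_report"] = str(out / "harmonization_report.tsv")
    atomic_write_frame(report_to_frame(result.records, result.report), paths["harmonization_report"])
    report_json = {
        "n_input": result.report.n_input,
        "n_mapped": result.report.n_mapped,
        "unmapped": [list(u) for u in result.report.unmapped],
    }
    paths["harmonization_report_json"] = str(out / "harmonization_report.json")
    atomic_write_text(json.dumps(report_json, indent=2), paths["harmonization_report_json"])

    manifest = {
        "config": config.to_dict(),
        "backend_content_hash": (
            backend.tables.content_hash() if isinstance(backend, TableBackend) else None
        ),
        "funnel": result.funnel,
    }
    paths["manifest"] = str(out / "run_manifest.json")
    atomic_write_text(json.dumps(manifest, indent=2, sort_keys=True), paths["manifest"])
    return paths
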