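"""Landscape analytics over a gene-patent link table.

Summaries are computed on the *deduplicated* patent set (key = full patent
number), except per-gene timelines which deduplicate within each gene
before the global dedup -- a patent shared by two genes appears in both
timelines but once in every global tally.  Classification tallies are
multi-label: a document classified C07D and C07K increments both
subclasses, so code counts may legitimately exceed the unique-patent
count.  Jurisdiction, grant-status and assignee-category tallies are
partitions and each sum exactly to the unique-patent count.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

import pandas as pd

from .model import (
    DEFAULT_APPLICATION_ONLY,
    GenePatentLink,
    PatentDocument,
    classification_subclass,
    is_granted,
)

UNKNOWN_YEAR = "unknown"

_DEFAULT_INDUSTRY = (
    "INC", "LTD", "LLC", "GMBH", "AG", "PHARMA", "THERAPEUTICS", "CORP",
    "SA", "BV", "PLC", "KGAA", "PHARMACEUTICALS", "BIOSCIENCES",
)
_DEFAULT_ACADEMIC = (
    "UNIVERSITY", "UNIV", "INSTITUTE", "COLLEGE", "HOSPITAL", "FOUNDATION",
    "CNRS", "ACADEMY", "INSERM", "SCHOOL",
)


@dataclass(frozen=True)
class AssigneeRules:
    """Keyword heuristic splitting assignees into industry / academic /
    individual.

    Matching is uppercase, word-boundary, across every name on a document;
    precedence is industry > academic > individual (corporate presence is
    the dominant signal on mixed assignee lists).  Documents with no
    assignee names, or none matching either list, fall back to individual.
    """

    industry_keywords: Tuple[str, ...] = _DEFAULT_INDUSTRY
    academic_keywords: Tuple[str, ...] = _DEFAULT_ACADEMIC

    def __post_init__(self) -> None:
        overlap = set(self.industry_keywords) & set(self.academic_keywords)
        if overlap:
            raise ValueError(f"assignee keyword lists overlap: {sorted(overlap)}")


def _keyword_re(keywords: Sequence[str]) -> re.Pattern:
    return re.compile(r"\b(" + "|".join(map(re.escape, keywords)) + r")\b")


def classify_assignee(names: Sequence[str], rules: AssigneeRules = AssigneeRules()) -> str:
    joined = " | ".join(n.upper() for n in names)
    if _keyword_re(rules.industry_keywords).search(joined):
        return "industry"
    if _keyword_re(rules.academic_keywords).search(joined):
        return "academic"
    return "individual"


@dataclass
class LandscapeSummary:
    """Aggregate patent landscape for one link table."""

    n_unique_patents: int
    by_jurisdiction: Dict[str, int]
    by_grant_status: Dict[str, int]
    by_class_subclass: Dict[str, int]
    by_year: Dict[str, int]
    by_assignee_category: Dict[str, int]
    per_gene_timeline: Dict[str, Dict[str, int]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_unique_patents": self.n_unique_patents,
                "by_jurisdiction": dict(sorted(self.by_jurisdiction.items())),
                "by_grant_status": dict(sorted(self.by_grant_status.items())),
                "by_class_subclass": dict(sorted(self.by_class_subclass.items())),
                "by_year": dict(sorted(self.by_year.items())),
                "by_assignee_category": dict(sorted(self.by_assignee_category.items())),
                "per_gene_timeline": {
                    g: dict(sorted(t.items()))
                    for g, t in sorted(self.per_gene_timeline.items())
                },
            },
            indent=2,
            sort_keys=False,
        )

    def check_partition_laws(self) -> None:
        """Self-audit: partition tallies must sum to the unique-patent count."""
        for name in ("by_jurisdiction", "by_grant_status", "by_assignee_category"):
            total = sum(getattr(self, name).values())
            if total != self.n_unique_patents:
                raise AssertionError(
                    f"{name} sums to {total}, expected {self.n_unique_patents}"
                )


def _year_key(doc: PatentDocument) -> str:
    return str(doc.year) if doc.year is not None else UNKNOWN_YEAR


def summarize(
    links: Sequence[GenePatentLink],
    rules: AssigneeRules = AssigneeRules(),
    application_only: FrozenSet[str] = DEFAULT_APPLICATION_ONLY,
) -> LandscapeSummary:
    """Compute all landscape tallies for a link table.

    Invariant under link-row permutation: every tally is computed from the
    set of unique documents (first occurrence wins for non-key fields,
    which for well-formed tables are identical anyway).
    """
    unique: Dict[tuple, PatentDocument] = {}
    for link in links:
        unique.setdefault(link.patent.key, link.patent)
    docs = list(unique.values())

    by_jurisdiction = Counter(d.identifier.authority for d in docs)
    by_grant = Counter(
        "granted" if is_granted(d.identifier, application_only) else "application"
        for d in docs
    )
    by_subclass: Counter = Counter()
    for d in docs:
        for sub in {classification_subclass(c) for c in d.classification_codes}:
            by_subclass[sub] += 1
    by_year = Counter(_year_key(d) for d in docs)
    by_assignee = Counter(classify_assignee(d.assignees, rules) for d in docs)

    per_gene: Dict[str, Dict[str, int]] = {}
    genes = sorted({l.gene for l in links})
    for gene in genes:
        per_gene[gene] = {
            str(y): c for y, c in gene_timeline(links, gene).items()
        }

    return LandscapeSummary(
        n_unique_patents=len(docs),
        by_jurisdiction=dict(by_jurisdiction),
        by_grant_status=dict(by_grant),
        by_class_subclass=dict(by_subclass),
        by_year=dict(by_year),
        by_assignee_category=dict(by_assignee),
        per_gene_timeline=per_gene,
    )


def gene_timeline(links: Sequence[GenePatentLink], gene: str) -> Dict[int, int]:
    """Per-year unique-patent counts for one gene.

    Patents are deduplicated within the gene before counting; years with
    zero patents are omitted, undated patents are skipped.  An unknown
    gene yields an empty mapping.
    """
    unique: Dict[tuple, PatentDocument] = {}
    for link in links:
        if link.gene == gene:
            unique.setdefault(link.patent.key, link.patent)
    years = Counter(d.year for d in unique.values() if d.year is not None)
    return dict(sorted(years.items()))


# --------------------------------------------------------------------------
# Serialization


def summary_to_long_frame(summary: LandscapeSummary) -> pd.DataFrame:
    """Long-format (dimension, key, count) table of all global tallies."""
    rows = [{"dimension": "total", "key": "unique_patents",
             "count": summary.n_unique_patents}]
    for dim, mapping in (
        ("jurisdiction", summary.by_jurisdiction),
        ("grant_status", summary.by_grant_status),
        ("class_subclass", summary.by_class_subclass),
        ("year", summary.by_year),
        ("assignee_category", summary.by_assignee_category),
    ):
        for key in sorted(mapping):
            rows.append({"dimension": dim, "key": str(key), "count": mapping[key]})
    return pd.DataFrame(rows, columns=["dimension", "key", "count"])


def timeline_to_frame(summary: LandscapeSummary) -> pd.DataFrame:
    rows = [
        {"gene": gene, "year": year, "count": count}
        for gene in sorted(summary.per_gene_timeline)
        for year, count in sorted(summary.per_gene_timeline[gene].items())
    ]
    return pd.DataFrame(rows, columns=["gene", "year", "count"])


def plot_summary(summary: LandscapeSummary, out_dir) -> List[str]:
    """Bar charts per landscape dimension (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for dim, mapping in (
        ("jurisdiction", summary.by_jurisdiction),
        ("grant_status", summary.by_grant_status),
        ("class_subclass", summary.by_class_subclass),
        ("year", summary.by_year),
        ("assignee_category", summary.by_assignee_category),
    ):
        if not mapping:
            continue
        keys = sorted(mapping)
        fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(keys)), 3))
        ax.bar(range(len(keys)), [mapping[k] for k in keys])
        ax.set_xticks(range(len(keys)))
        ax.set_xticklabels(keys, rotation=60, ha="right", fontsize=7)
        ax.set_ylabel("unique patents")
        ax.set_title(dim)
        fig.tight_layout()
        path = out / f"landscape_{dim}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
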