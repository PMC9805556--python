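"""Data backends and the seeded synthetic fixture generator.

Every backend answers the same four read-only lookups the pipeline needs:

1. ``query_gene_xref(symbol)``      -- gene symbol -> (UniProt, ChEMBL target)
2. ``query_activities(target_id)``  -- target -> bioactivity evidence rows
3. ``query_compound_xref(chembl_id)`` -- compound -> patent-chemistry id
4. ``query_patents(surechembl_id)`` -- patent-chemistry id -> patent documents

"Absent" is a normal answer (empty result / ``None``), never an error; a
broken store raises :class:`BackendError` instead.  A live web-service
client would satisfy the same contract, but the offline backends below --
a directory of four TSV files or a single-file SQLite store -- are the
supported, testable surface.

The fixture generator plants a known gene -> modulator -> patent graph with
configurable attrition at every hop (unmapped genes, non-qualifying
evidence, compounds without a patent-chemistry cross-reference, patents
outside the classification whitelist) and returns ground-truth counts
computed by exhaustively joining the emitted tables, so a pipeline run can
be audited against what was actually planted rather than against sampling
intentions.
"""

from __future__ import annotations

import json
import sqlite3
from abc import ABC, abstractmethod
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Dict, FrozenSet, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    ActivityEvidence,
    PatentDocument,
    PatentNumberError,
    classification_matches,
    parse_patent_number,
)

TABLE_NAMES = ("gene_xref", "activity", "compound_xref", "patent_occurrence")

_COLUMNS = {
    "gene_xref": ["symbol", "uniprot_id", "chembl_target_id"],
    "activity": ["compound_id", "target_id", "assay_type", "action", "potency_value"],
    "compound_xref": ["chembl_id", "surechembl_id", "modality"],
    "patent_occurrence": [
        "surechembl_id",
        "authority",
        "serial",
        "kind",
        "classification_codes",
        "publication_date",
        "assignees",
    ],
}

#: Default classification whitelist shared with the patent extractor: drug
#: formulations (A61K), therapeutic activity (A61P), organic chemistry
#: (C07), biochemistry/microbiology (C12) and combinatorial libraries (C40B).
DEFAULT_WHITELIST_PREFIXES: Tuple[str, ...] = ("A61K", "A61P", "C07", "C12", "C40B")


class BackendError(RuntimeError):
    """The data store itself is broken or unreachable (distinct from 'not found')."""


class ConfigurationError(ValueError):
    """Invalid fixture-plan or run-configuration parameters."""


# --------------------------------------------------------------------------
# Relational snapshot


@dataclass
class BackendTables:
    """The four reference tables as pandas DataFrames.

    Null is the empty string in all string columns (matching the on-disk TSV
    convention); list-valued cells (classification codes, assignees) are
    ";"-joined.  Primary keys: ``symbol`` in gene_xref, ``chembl_id`` in
    compound_xref, ``(surechembl_id, authority, serial, kind)`` in
    patent_occurrence.
    """

    gene_xref: pd.DataFrame
    activity: pd.DataFrame
    compound_xref: pd.DataFrame
    patent_occurrence: pd.DataFrame

    def validate(self) -> None:
        for name in TABLE_NAMES:
            frame = getattr(self, name)
            missing = set(_COLUMNS[name]) - set(frame.columns)
            if missing:
                raise BackendError(f"table {name} missing columns {sorted(missing)}")
        if self.gene_xref["symbol"].duplicated().any():
            raise BackendError("gene_xref: duplicate symbol (primary key)")
        if self.compound_xref["chembl_id"].duplicated().any():
            raise BackendError("compound_xref: duplicate chembl_id (primary key)")
        pk = ["surechembl_id", "authority", "serial", "kind"]
        if self.patent_occurrence[pk].duplicated().any():
            raise BackendError("patent_occurrence: duplicate (surechembl_id, number)")

    def content_hash(self) -> str:
        """SHA-256 over the canonically serialized tables (provenance stamp)."""
        import hashlib

        h = hashlib.sha256()
        for name in TABLE_NAMES:
            frame = getattr(self, name)[_COLUMNS[name]]
            h.update(name.encode())
            h.update(frame.to_csv(sep="\t", index=False).encode())
        return h.hexdigest()


class CompoundXref(NamedTuple):
    chembl_id: str
    surechembl_id: Optional[str]
    modality: str


class GeneXrefRow(NamedTuple):
    symbol: str
    uniprot_id: Optional[str]
    chembl_target_id: Optional[str]


def _null(value) -> Optional[str]:
    """Empty string / NaN -> None."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value)
    return text if text else None


class Backend(ABC):
    """The four-query read contract every data backend satisfies."""

    @abstractmethod
    def query_gene_xref(self, symbol: str) -> List[GeneXrefRow]:
        """Cross-reference rows for a symbol; empty list = absent."""

    @abstractmethod
    def query_activities(self, target_id: str) -> List[ActivityEvidence]:
        """All bioactivity evidence rows against a target; empty = absent."""

    @abstractmethod
    def query_compound_xref(self, chembl_id: str) -> Optional[CompoundXref]:
        """Compound cross-reference row, or None if absent."""

    @abstractmethod
    def query_patents(self, surechembl_id: str) -> List[PatentDocument]:
        """Patent documents referencing a patent-chemistry id; empty = absent."""


class TableBackend(Backend):
    """In-memory backend over a :class:`BackendTables` snapshot.

    Indexes are built once at construction so lookups are dictionary reads;
    results depend only on the snapshot contents.
    """

    def __init__(self, tables: BackendTables):
        tables.validate()
        self.tables = tables
        self._genes: Dict[str, List[GeneXrefRow]] = {}
        for row in tables.gene_xref.itertuples(index=False):
            self._genes.setdefault(str(row.symbol), []).append(
                GeneXrefRow(str(row.symbol), _null(row.uniprot_id), _null(row.chembl_target_id))
            )
        self._activities: Dict[str, List[ActivityEvidence]] = {}
        for row in tables.activity.itertuples(index=False):
            potency = row.potency_value
            if potency is not None and potency != "" and not (
                isinstance(potency, float) and np.isnan(potency)
            ):
                potency = float(potency)
            else:
                potency = None
            ev = ActivityEvidence(
                compound_id=str(row.compound_id),
                target_id=str(row.target_id),
                assay_type=str(row.assay_type),
                action=str(row.action),
                potency_value=potency,
            )
            self._activities.setdefault(ev.target_id, []).append(ev)
        self._compounds: Dict[str, CompoundXref] = {}
        for row in tables.compound_xref.itertuples(index=False):
            self._compounds[str(row.chembl_id)] = CompoundXref(
                str(row.chembl_id), _null(row.surechembl_id), str(row.modality)
            )
        self._patents: Dict[str, List[PatentDocument]] = {}
        for i, row in enumerate(tables.patent_occurrence.itertuples(index=False)):
            try:
                doc = _row_to_document(row)
            except PatentNumberError as exc:
                raise PatentNumberError(
                    exc.component,
                    f"patent_occurrence row {i} "
                    f"(surechembl_id={row.surechembl_id!r}): {exc}",
                ) from exc
            self._patents.setdefault(str(row.surechembl_id), []).append(doc)

    def query_gene_xref(self, symbol: str) -> List[GeneXrefRow]:
        return list(self._genes.get(symbol, []))

    def query_activities(self, target_id: str) -> List[ActivityEvidence]:
        return list(self._activities.get(target_id, []))

    def query_compound_xref(self, chembl_id: str) -> Optional[CompoundXref]:
        return self._compounds.get(chembl_id)

    def query_patents(self, surechembl_id: str) -> List[PatentDocument]:
        return list(self._patents.get(surechembl_id, []))


def _row_to_document(row) -> PatentDocument:
    identifier = parse_patent_number(f"{row.authority}-{row.serial}-{row.kind}")
    codes = frozenset(c for c in str(row.classification_codes or "").split(";") if c)
    pub = _null(row.publication_date)
    pub_date = date.fromisoformat(pub) if pub else None
    assignees = tuple(a for a in str(row.assignees or "").split(";") if a)
    return PatentDocument(
        identifier=identifier,
        classification_codes=codes,
        publication_date=pub_date,
        assignees=assignees,
    )


# --------------------------------------------------------------------------
# On-disk stores: a directory of four TSVs, or one SQLite file.


def write_tables_tsv(tables: BackendTables, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in TABLE_NAMES:
        frame = getattr(tables, name)[_COLUMNS[name]]
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)


def read_tables_tsv(in_dir) -> BackendTables:
    path = Path(in_dir)
    frames = {}
    for name in TABLE_NAMES:
        file = path / f"{name}.tsv"
        if not file.exists():
            raise BackendError(f"backend directory {path} is missing {name}.tsv")
        try:
            frames[name] = pd.read_csv(
                file, sep="\t", dtype=str, keep_default_na=False
            )
        except Exception as exc:  # malformed store, not "not found"
            raise BackendError(f"cannot read {file}: {exc}") from exc
    return BackendTables(**frames)


def write_tables_sqlite(tables: BackendTables, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with sqlite3.connect(path) as con:
        for name in TABLE_NAMES:
            frame = getattr(tables, name)[_COLUMNS[name]].astype(str)
            frame.to_sql(name, con, if_exists="replace", index=False)


def read_tables_sqlite(path) -> BackendTables:
    path = Path(path)
    if not path.exists():
        raise BackendError(f"no such backend store: {path}")
    try:
        with sqlite3.connect(path) as con:
            frames = {
                name: pd.read_sql(f"SELECT * FROM {name}", con).fillna("").astype(str)
                for name in TABLE_NAMES
            }
    except (sqlite3.Error, pd.errors.DatabaseError) as exc:
        raise BackendError(f"cannot read SQLite store {path}: {exc}") from exc
    return BackendTables(**frames)


def load_backend(path) -> TableBackend:
    """Open an offline backend, auto-detecting the store format by path.

    A directory is read as four TSV files; a file as a SQLite store.
    """
    p = Path(path)
    if p.is_dir():
        return TableBackend(read_tables_tsv(p))
    if p.is_file():
        return TableBackend(read_tables_sqlite(p))
    raise BackendError(f"backend path does not exist: {p}")


# --------------------------------------------------------------------------
# Fixture generator


@dataclass(frozen=True)
class FixturePlan:
    """Sampling plan for a synthetic gene->modulator->patent graph.

    Defaults emulate the attrition profile of a rare-disease patent
    landscape: 56 input genes of which ~21% resolve to activity-bearing
    targets, ~30% of validated compounds carrying a patent-chemistry
    cross-reference, and ~2/3 of mappable compounds linked to at least one
    whitelisted patent, with publications spread over 2000-2021 across the
    US/EP/WO jurisdictions in roughly 83:19:33 proportion.
    """

    n_genes: int = 56
    frac_gene_mapped: float = 12 / 56
    modulators_per_gene: Tuple[int, int] = (1, 78)
    evidence_per_compound: Tuple[int, int] = (1, 3)
    frac_evidence_allowed: float = 0.9
    frac_compound_mapped: float = 143 / 469
    patents_per_compound: Tuple[int, int] = (0, 2)
    frac_patent_whitelisted: float = 0.9
    year_range: Tuple[int, int] = (2000, 2021)
    jurisdiction_weights: Dict[str, float] = field(
        default_factory=lambda: {"US": 83.0, "EP": 19.0, "WO": 33.0}
    )
    allowed_assay_types: FrozenSet[str] = frozenset({"B", "F"})
    whitelist_prefixes: Tuple[str, ...] = DEFAULT_WHITELIST_PREFIXES
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        for name in (
            "frac_gene_mapped",
            "frac_evidence_allowed",
            "frac_compound_mapped",
            "frac_patent_whitelisted",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name in ("modulators_per_gene", "evidence_per_compound", "patents_per_compound"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ConfigurationError(f"{name} range ({lo}, {hi}) is empty or negative")
        if self.modulators_per_gene[1] < 1:
            raise ConfigurationError("modulators_per_gene upper bound must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigurationError(f"year_range {self.year_range} is empty")
        if not self.jurisdiction_weights or any(
            w < 0 for w in self.jurisdiction_weights.values()
        ):
            raise ConfigurationError("jurisdiction_weights must be non-empty, non-negative")
        if sum(self.jurisdiction_weights.values()) <= 0:
            raise ConfigurationError("jurisdiction_weights must have positive total")
        if not self.allowed_assay_types:
            raise ConfigurationError("allowed_assay_types must be non-empty")
        if not self.whitelist_prefixes:
            raise ConfigurationError("whitelist_prefixes must be non-empty")


@dataclass
class FixtureTruth:
    """Planted ground truth, computed by exhaustive join over the tables.

    ``per_gene`` maps each mapped symbol to its validated / patent-mappable
    modulator counts and its unique whitelisted patent count; ``totals``
    aggregates the funnel (unique patents deduplicated globally by full
    patent number).
    """

    per_gene: Dict[str, Dict[str, int]]
    totals: Dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {"per_gene": self.per_gene, "totals": self.totals}, indent=2, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "FixtureTruth":
        data = json.loads(text)
        return cls(per_gene=data["per_gene"], totals=data["totals"])


# Disallowed assay codes seen in real evidence sets: A(DMET), T(ox), P(hyschem), U.
_OTHER_ASSAY_TYPES = ("A", "T", "P", "U")

# Subclass pools for planted classification codes.  The whitelisted pool
# spans the subclasses a pharmaceutical landscape exhibits (heterocyclics,
# peptides, nucleic-acid assays, ...); the other pool is deliberately
# outside every default whitelist prefix.
_WHITELISTED_SUBCLASSES = (
    "C07D", "C07K", "C12Q", "C07H", "A61P", "C12P", "C07F", "C07C", "A61K", "C40B",
)
_OTHER_SUBCLASSES = ("G06F", "G01N", "H04L", "B60K", "F16H", "E04B")

_INDUSTRY_ASSIGNEES = (
    "ACME THERAPEUTICS INC",
    "NOVION PHARMA AG",
    "HELIX BIOSCIENCES LTD",
    "ORPHANIX CORP",
    "BLUEGENE PHARMA GMBH",
    "VERTEXA LLC",
)
_ACADEMIC_ASSIGNEES = (
    "UNIVERSITY OF BONN",
    "KAROLINSKA INSTITUTE",
    "STATE COLLEGE OF MEDICINE",
    "CHILDRENS HOSPITAL RESEARCH FOUNDATION",
    "NATIONAL ACADEMY OF SCIENCES",
)
_INDIVIDUAL_ASSIGNEES = (
    "JANE DOE",
    "JOHN SMITH",
    "MARIA GARCIA",
    "WEI ZHANG",
    "AMARA OKAFOR",
)


def _draw_serial(rng: np.random.Generator, used: set) -> str:
    """Unique 7-11 digit serial; lengths weighted toward the common 7-10."""
    while True:
        length = int(rng.choice([7, 8, 10, 11], p=[0.3, 0.3, 0.3, 0.1]))
        digits = rng.integers(0, 10, size=length)
        serial = "".join(map(str, digits))
        if serial not in used:
            used.add(serial)
            return serial


def _draw_code(rng: np.random.Generator, subclasses: Sequence[str]) -> str:
    sub = str(rng.choice(list(subclasses)))
    return f"{sub} {int(rng.integers(1, 500))}/{int(rng.integers(0, 100)):02d}"


def generate_fixture(plan: FixturePlan) -> Tuple[BackendTables, FixtureTruth]:
    """Plant a synthetic relational snapshot and return it with its truth.

    Deterministic for a given plan (each table uses its own random stream
    seeded from ``plan.seed`` plus a fixed offset, so changing one
    dimension of the plan does not perturb draws in unrelated tables).
    Serial numbers are drawn without replacement within the fixture, so
    patent-number collisions cannot silently alter deduplication counts.
    The returned truth is computed from the emitted tables by exhaustive
    join (see :func:`compute_truth`), not from the sampling intentions.
    """
    plan.validate()
    rng_gene = np.random.default_rng(plan.seed + 1)
    rng_act = np.random.default_rng(plan.seed + 2)
    rng_cmp = np.random.default_rng(plan.seed + 3)
    rng_pat = np.random.default_rng(plan.seed + 4)

    juris = sorted(plan.jurisdiction_weights)
    jweights = np.array([plan.jurisdiction_weights[j] for j in juris], dtype=float)
    jweights = jweights / jweights.sum()

    gene_rows, act_rows, cmp_rows, pat_rows = [], [], [], []
    used_serials: set = set()
    compound_counter = 0

    for g in range(plan.n_genes):
        symbol = f"GENE{g + 1:04d}"
        mapped = rng_gene.random() < plan.frac_gene_mapped
        if not mapped:
            # Unmapped genes fail at either hop: no protein accession at
            # all, or an accession without a target cross-reference.
            if rng_gene.random() < 0.5:
                gene_rows.append((symbol, "", ""))
            else:
                gene_rows.append((symbol, f"P{g + 1:05d}", ""))
            continue
        uniprot = f"P{g + 1:05d}"
        target = f"CHEMBLT{g + 1:04d}"
        gene_rows.append((symbol, uniprot, target))

        lo, hi = plan.modulators_per_gene
        n_mods = int(rng_act.integers(lo, hi + 1))
        for _ in range(n_mods):
            compound_counter += 1
            chembl_id = f"CHEMBL{compound_counter:06d}"
            elo, ehi = plan.evidence_per_compound
            n_ev = max(1, int(rng_act.integers(elo, ehi + 1)))
            for _ in range(n_ev):
                if rng_act.random() < plan.frac_evidence_allowed:
                    assay = str(rng_act.choice(sorted(plan.allowed_assay_types)))
                else:
                    assay = str(rng_act.choice(_OTHER_ASSAY_TYPES))
                action = str(
                    rng_act.choice(
                        ["activation", "inhibition", "other", "unknown"],
                        p=[0.2, 0.6, 0.1, 0.1],
                    )
                )
                potency = (
                    round(float(rng_act.uniform(4.0, 10.0)), 2)
                    if rng_act.random() < 0.8
                    else ""
                )
                act_rows.append((chembl_id, target, assay, action, potency))

            modality = str(
                rng_cmp.choice(["small_molecule", "biological"], p=[0.85, 0.15])
            )
            if rng_cmp.random() < plan.frac_compound_mapped:
                schembl = f"SCHEMBL{compound_counter:06d}"
                cmp_rows.append((chembl_id, schembl, modality))
            else:
                cmp_rows.append((chembl_id, "", modality))
                continue

            plo, phi = plan.patents_per_compound
            n_pat = int(rng_pat.integers(plo, phi + 1))
            for _ in range(n_pat):
                authority = str(juris[int(rng_pat.choice(len(juris), p=jweights))])
                serial = _draw_serial(rng_pat, used_serials)
                # Application-only offices never emit B-kind documents.
                if authority == "WO":
                    kind = str(rng_pat.choice(["A1", "A2"], p=[0.8, 0.2]))
                else:
                    kind = str(
                        rng_pat.choice(["A1", "A2", "B1", "B2"], p=[0.5, 0.2, 0.2, 0.1])
                    )
                n_codes = int(rng_pat.integers(1, 4))
                whitelisted = rng_pat.random() < plan.frac_patent_whitelisted
                codes = []
                if whitelisted:
                    codes.append(_draw_code(rng_pat, _WHITELISTED_SUBCLASSES))
                    for _ in range(n_codes - 1):
                        pool = (
                            _WHITELISTED_SUBCLASSES
                            if rng_pat.random() < 0.7
                            else _OTHER_SUBCLASSES
                        )
                        codes.append(_draw_code(rng_pat, pool))
                else:
                    for _ in range(n_codes):
                        codes.append(_draw_code(rng_pat, _OTHER_SUBCLASSES))
                y0, y1 = plan.year_range
                day0 = date(y0, 1, 1)
                span = (date(y1, 12, 31) - day0).days
                pub = day0 + timedelta(days=int(rng_pat.integers(0, span + 1)))
                category = rng_pat.choice(
                    ["industry", "academic", "individual"],
                    p=np.array([85.0, 23.0, 25.0]) / 133.0,
                )
                if category == "industry":
                    names = [str(rng_pat.choice(_INDUSTRY_ASSIGNEES))]
                    if rng_pat.random() < 0.3:
                        names.append(str(rng_pat.choice(_INDIVIDUAL_ASSIGNEES)))
                elif category == "academic":
                    names = [str(rng_pat.choice(_ACADEMIC_ASSIGNEES))]
                else:
                    names = [str(rng_pat.choice(_INDIVIDUAL_ASSIGNEES))]
                pat_rows.append(
                    (
                        schembl,
                        authority,
                        serial,
                        kind,
                        ";".join(dict.fromkeys(codes)),
                        pub.isoformat(),
                        ";".join(names),
                    )
                )

    tables = BackendTables(
        gene_xref=pd.DataFrame(gene_rows, columns=_COLUMNS["gene_xref"]),
        activity=pd.DataFrame(act_rows, columns=_COLUMNS["activity"]),
        compound_xref=pd.DataFrame(cmp_rows, columns=_COLUMNS["compound_xref"]),
        patent_occurrence=pd.DataFrame(pat_rows, columns=_COLUMNS["patent_occurrence"]),
    )
    for name in TABLE_NAMES:  # uniform string dtype, "" = null
        setattr(tables, name, getattr(tables, name).astype(str))
    truth = compute_truth(tables, plan.allowed_assay_types, plan.whitelist_prefixes)
    return tables, truth


def compute_truth(
    tables: BackendTables,
    allowed_assay_types: FrozenSet[str] = frozenset({"B", "F"}),
    whitelist_prefixes: Sequence[str] = DEFAULT_WHITELIST_PREFIXES,
) -> FixtureTruth:
    """Exhaustive join over the emitted tables with the stage filters applied.

    Stage semantics: a modulator is *validated* if it has >= 1 evidence row
    with an allowed assay type against a mapped gene's target; *mappable*
    if additionally cross-referenced to a patent-chemistry id; a patent
    counts if >= 1 of its classification codes matches the whitelist, and
    unique patents are keyed by the full (authority, serial, kind) number.
    """
    genes = tables.gene_xref
    mapped = genes[(genes["uniprot_id"] != "") & (genes["chembl_target_id"] != "")]

    per_gene: Dict[str, Dict[str, int]] = {}
    global_validated = 0
    global_mappable = 0
    global_with_patents = 0
    global_patent_keys = set()
    genes_with_mods = 0
    genes_with_patents = 0

    act = tables.activity
    cx = tables.compound_xref.set_index("chembl_id")
    pat_by_schembl: Dict[str, list] = {}
    for row in tables.patent_occurrence.itertuples(index=False):
        pat_by_schembl.setdefault(row.surechembl_id, []).append(row)

    for grow in mapped.itertuples(index=False):
        target = grow.chembl_target_id
        rows = act[(act["target_id"] == target) & act["assay_type"].isin(allowed_assay_types)]
        validated = sorted(rows["compound_id"].unique())
        mappable = []
        for cid in validated:
            if cid in cx.index and cx.loc[cid, "surechembl_id"] != "":
                mappable.append((cid, cx.loc[cid, "surechembl_id"]))
        gene_patent_keys = set()
        n_with_patents = 0
        for _cid, sid in mappable:
            keys = set()
            for prow in pat_by_schembl.get(sid, []):
                codes = [c for c in prow.classification_codes.split(";") if c]
                if any(
                    classification_matches(code, entry)
                    for code in codes
                    for entry in whitelist_prefixes
                ):
                    keys.add((prow.authority, prow.serial, prow.kind))
            if keys:
                n_with_patents += 1
            gene_patent_keys |= keys
        per_gene[grow.symbol] = {
            "n_modulators_validated": len(validated),
            "n_modulators_mappable": len(mappable),
            "n_modulators_with_patents": n_with_patents,
            "n_patents_whitelisted_unique": len(gene_patent_keys),
        }
        global_validated += len(validated)
        global_mappable += len(mappable)
        global_with_patents += n_with_patents
        global_patent_keys |= gene_patent_keys
        if validated:
            genes_with_mods += 1
        if gene_patent_keys:
            genes_with_patents += 1

    totals = {
        "n_genes": int(len(genes)),
        "n_genes_mapped": int(len(mapped)),
        "n_genes_with_modulators": genes_with_mods,
        "n_genes_with_patents": genes_with_patents,
        "n_modulators_validated": global_validated,
        "n_modulators_mappable": global_mappable,
        "n_modulators_with_patents": global_with_patents,
        "n_patents_whitelisted_unique": len(global_patent_keys),
    }
    return FixtureTruth(per_gene=per_gene, totals=totals)


def write_fixture(
    tables: BackendTables, truth: FixtureTruth, out_dir, fmt: str = "tsv"
) -> Path:
    """Write a fixture to disk (TSV directory or SQLite file) plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        write_tables_tsv(tables, out)
        backend_path = out
    elif fmt == "sqlite":
        backend_path = out / "backend.sqlite"
        write_tables_sqlite(tables, backend_path)
    else:
        raise ConfigurationError(f"unknown fixture format {fmt!r}")
    (out / "truth.json").write_text(truth.to_json())
    return backend_path
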