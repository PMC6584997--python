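"""Readers and writers for the pipeline's tabular inputs.

Five evidence-source dialects (GWAS-catalog-like, PheWAS-catalog-like,
HMDB-derived metabolite-protein tables, plain gene lists for transcriptomics
and biomedical sources) plus DrugBank-style drug-target tables, trial lists
and pathogenesis (GOF/LOF) annotation tables are harmonized into the shared
domain types.  Tables are accepted as TSV or CSV (sniffed by extension, then
by delimiter); a header row is required.  Column names are matched through a
configurable synonym map so that exports from different catalog versions
parse without editing.

Row-level problems (an unparseable p-value, say) are collected into a
rejects report and the row is skipped; structural problems (a missing
mandatory column) raise :class:`FormatError`.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .types import (
    Action,
    Direction,
    DrugGroup,
    DrugTargetRecord,
    EvidenceRecord,
    MetaboliteAssociation,
    PathogenesisAnnotation,
    Role,
    Source,
    TargetCategory,
    TrialRecord,
    harmonize_symbol,
)

logger = logging.getLogger("melanoseek.evidence_io")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A structural problem with an input table (missing column, bad header)."""


class InputDataError(ValueError):
    """Semantically invalid input (e.g. conflicting pathogenesis directions)."""


@dataclass(frozen=True)
class RejectedRow:
    path: str
    row_index: int
    reason: str


# Default column-name synonyms, all compared after lowercasing and
# normalising separators.  Override via the `synonyms` argument.
DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "trait": ("trait", "disease trait", "disease/trait", "phenotype", "phewas phenotype"),
    "gene": ("gene", "genes", "mapped gene", "reported gene", "gene name", "nearest gene"),
    "snp": ("snp", "snps", "snp id", "rsid", "variant"),
    "p_value": ("p", "p value", "pvalue", "p-value"),
    "citation": ("pubmed id", "pmid", "citation", "study"),
    "metabolite": ("metabolite", "metabolite name", "compound"),
    "protein": ("protein", "gene", "symbol", "protein name"),
    "role": ("role", "type", "protein type"),
    "drug": ("drug", "drug name", "name"),
    "drug_id": ("drug id", "drugbank id", "accession", "id"),
    "group": ("group", "groups", "drug group", "status"),
    "target": ("target", "target name", "target gene", "gene"),
    "target_category": ("target category", "category", "target type"),
    "actions": ("action", "actions", "mode of action", "action mode"),
    "indication": ("indication", "indications", "current indication"),
    "stage": ("stage", "phase", "trial stage"),
    "condition": ("condition", "disease", "trial condition"),
    "direction": ("direction", "pathogenesis", "gof lof", "function"),
    "description": ("description", "notes"),
    "provenance": ("provenance", "source", "evidence source"),
}


def _norm_header(name: str) -> str:
    return re.sub(r"[\s_\-/]+", " ", str(name).strip().lower())


def read_table(path: PathLike) -> pd.DataFrame:
    """Read a delimited table, sniffing TSV vs CSV by extension then content."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".tab", ".txt"}:
        sep: Optional[str] = "\t"
    elif suffix == ".csv":
        sep = ","
    else:
        with open(path, newline="") as fh:
            sample = fh.read(4096)
        try:
            sep = csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
        except csv.Error:
            sep = "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.columns.size == 0:
        raise FormatError(f"{path}: no header row")
    return df


def _resolve_columns(
    df: pd.DataFrame,
    required: Sequence[str],
    optional: Sequence[str] = (),
    synonyms: Optional[dict[str, tuple[str, ...]]] = None,
    path: PathLike = "<table>",
) -> dict[str, str]:
    """Map canonical field names to actual dataframe columns via synonyms."""
    syn = dict(DEFAULT_SYNONYMS)
    if synonyms:
        syn.update(synonyms)
    normed = {_norm_header(c): c for c in df.columns}
    out: dict[str, str] = {}
    for field in list(required) + list(optional):
        for cand in syn.get(field, (field,)):
            if _norm_header(cand) in normed:
                out[field] = normed[_norm_header(cand)]
                break
        else:
            if field in required:
                raise FormatError(
                    f"{path}: missing mandatory column '{field}' "
                    f"(accepted names: {', '.join(syn.get(field, (field,)))})"
                )
    return out


# Intergenic labels like "TERT - CLPTM1L" name two flanking genes; a spaced
# hyphen is the separator so hyphenated symbols (HLA-B) survive intact.
_GENE_SPLIT = re.compile(r"[,;]|\s+-\s+|\sx\s")


def split_gene_cell(cell: str) -> list[str]:
    """Explode a multi-gene cell into individual harmonized symbols."""
    parts = [harmonize_symbol(p) for p in _GENE_SPLIT.split(cell)]
    return [p for p in parts if p]


def _parse_p(cell: str) -> float:
    p = float(cell)
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p-value {p} outside (0, 1]")
    return p


def _parse_association_evidence(
    path: PathLike,
    source: Source,
    traits: Iterable[str],
    p_max: float,
    synonyms: Optional[dict[str, tuple[str, ...]]],
    rejects: Optional[list[RejectedRow]],
) -> list[EvidenceRecord]:
    df = read_table(path)
    cols = _resolve_columns(
        df, required=["trait", "gene", "snp", "p_value"], optional=["citation"],
        synonyms=synonyms, path=path,
    )
    wanted = {t.strip().lower() for t in traits}
    records: list[EvidenceRecord] = []
    n_rejected = 0
    for idx, row in df.iterrows():
        trait = str(row[cols["trait"]]).strip()
        if trait.lower() not in wanted:
            continue
        try:
            p = _parse_p(row[cols["p_value"]])
        except (TypeError, ValueError) as exc:
            n_rejected += 1
            if rejects is not None:
                rejects.append(RejectedRow(str(path), int(idx), f"bad p-value: {exc}"))
            continue
        if p > p_max:
            continue
        snp = str(row[cols["snp"]]).strip() or None
        citation = (
            str(row[cols["citation"]]).strip() or None if "citation" in cols else None
        )
        for gene in split_gene_cell(str(row[cols["gene"]])):
            records.append(
                EvidenceRecord(
                    gene=gene, source=source, trait=trait, p_value=p,
                    snp_id=snp, citation=citation,
                )
            )
    logger.info(
        "%s: %d records accepted, %d rows rejected", path, len(records), n_rejected
    )
    return records


def parse_gwas_evidence(
    path: PathLike,
    traits: Iterable[str] = ("melanoma", "cutaneous malignant melanoma"),
    p_max: float = 1.0,
    synonyms: Optional[dict[str, tuple[str, ...]]] = None,
    rejects: Optional[list[RejectedRow]] = None,
) -> list[EvidenceRecord]:
    """Parse a GWAS-catalog-style table into GWAS evidence records.

    Rows are kept when their trait matches ``traits`` case-insensitively and
    their allelic-association p-value is at most ``p_max`` (inclusive).  The
    default ``p_max`` of 1.0 does not enforce a significance cut: catalog
    exports are already thresholded upstream, so the observed maximum is a
    property of the input rather than a filter here.  Multi-gene cells are
    exploded into one record per gene.
    """
    return _parse_association_evidence(path, Source.GWAS, traits, p_max, synonyms, rejects)


def parse_phewas_evidence(
    path: PathLike,
    phenotypes: Iterable[str] = ("melanoma", "skin cancer"),
    p_max: float = 0.05,
    synonyms: Optional[dict[str, tuple[str, ...]]] = None,
    rejects: Optional[list[RejectedRow]] = None,
) -> list[EvidenceRecord]:
    """Parse a PheWAS-catalog-style table; phenotype filter plus p <= p_max (default 0.05)."""
    return _parse_association_evidence(
        path, Source.PHEWAS, phenotypes, p_max, synonyms, rejects
    )


def parse_metabolite_table(
    path: PathLike,
    synonyms: Optional[dict[str, tuple[str, ...]]] = None,
) -> tuple[list[MetaboliteAssociation], list[EvidenceRecord]]:
    """Parse metabolite-protein associations; also emit one evidence record per protein.

    Duplicate (metabolite, protein, role) rows are dropped.  An unknown role
    token maps to UNKNOWN with a warning rather than rejecting the row.
    """
    df = read_table(path)
    cols = _resolve_columns(
        df, required=["metabolite", "protein"], optional=["role"],
        synonyms=synonyms, path=path,
    )
    assocs: list[MetaboliteAssociation] = []
    seen: set[tuple[str, str, Role]] = set()
    proteins: dict[str, tuple[str, Role]] = {}
    for _, row in df.iterrows():
        metabolite = str(row[cols["metabolite"]]).strip()
        protein = harmonize_symbol(str(row[cols["protein"]]))
        if not metabolite or not protein:
            continue
        role_token = str(row[cols["role"]]).strip().upper() if "role" in cols else ""
        if not role_token:
            role = Role.UNKNOWN
        else:
            try:
                role = Role(role_token)
            except ValueError:
                logger.warning("%s: unknown role %r mapped to UNKNOWN", path, role_token)
                role = Role.UNKNOWN
        key = (metabolite, protein, role)
        if key in seen:
            continue
        seen.add(key)
        assocs.append(MetaboliteAssociation(metabolite=metabolite, protein=protein, role=role))
        proteins.setdefault(protein, (metabolite, role))
    evidence = [
        EvidenceRecord(
            gene=protein, source=Source.METABOLOMICS, metabolite=met, role=role
        )
        for protein, (met, role) in sorted(proteins.items())
    ]
    logger.info("%s: %d associations, %d unique proteins", path, len(assocs), len(evidence))
    return assocs, evidence


def parse_gene_list(path: PathLike, source: Source) -> list[EvidenceRecord]:
    """Parse a one-symbol-per-line (or one-column) gene list.

    Symbols are harmonized and deduplicated; a blank file yields an empty list.
    """
    path = Path(path)
    genes: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    # Tolerate a header line such as "gene" in one-column tables.
    if lines and _norm_header(lines[0]) in {"gene", "symbol", "gene name"}:
        lines = lines[1:]
    for ln in lines:
        sym = harmonize_symbol(ln)
        if sym and sym not in seen:
            seen.add(sym)
            genes.append(sym)
    return [EvidenceRecord(gene=g, source=source) for g in genes]


def _parse_actions(cell: str) -> frozenset[Action]:
    tokens = [t.strip().upper() for t in re.split(r"[,;/]", str(cell)) if t.strip()]
    actions: set[Action] = set()
    for tok in tokens:
        try:
            actions.add(Action(tok))
        except ValueError:
            logger.warning("unknown action %r mapped to UNKNOWN", tok)
            actions.add(Action.UNKNOWN)
    if not actions:
        actions.add(Action.UNKNOWN)
    return frozenset(actions)


def parse_drug_targets(
    path: PathLike,
    synonyms: Optional[dict[str, tuple[str, ...]]] = None,
) -> list[DrugTargetRecord]:
    """Parse a DrugBank-style drug-target table."""
    df = read_table(path)
    cols = _resolve_columns(
        df,
        required=["drug", "drug_id", "group", "target", "target_category", "actions"],
        optional=["indication"],
        synonyms=synonyms,
        path=path,
    )
    records: list[DrugTargetRecord] = []
    for _, row in df.iterrows():
        try:
            group = DrugGroup(str(row[cols["group"]]).strip().upper())
            category = TargetCategory(str(row[cols["target_category"]]).strip().upper())
        except ValueError as exc:
            raise InputDataError(f"{path}: {exc}") from exc
        records.append(
            DrugTargetRecord(
                drug=str(row[cols["drug"]]).strip(),
                drug_id=str(row[cols["drug_id"]]).strip(),
                group=group,
                target=harmonize_symbol(str(row[cols["target"]])),
                target_category=category,
                actions=_parse_actions(row[cols["actions"]]),
                indication=str(row[cols["indication"]]).strip() if "indication" in cols else "",
            )
        )
    logger.info("%s: %d drug-target records", path, len(records))
    return records


def parse_trials(
    path: PathLike,
    synonyms: Optional[dict[str, tuple[str, ...]]] = None,
) -> list[TrialRecord]:
    """Parse a known-indication (clinical trial) drug list."""
    df = read_table(path)
    cols = _resolve_columns(
        df, required=["drug"], optional=["stage", "condition"], synonyms=synonyms, path=path
    )
    records = []
    for _, row in df.iterrows():
        drug = str(row[cols["drug"]]).strip()
        if not drug:
            continue
        records.append(
            TrialRecord(
                drug=drug,
                stage=str(row[cols["stage"]]).strip() if "stage" in cols else "",
                condition=str(row[cols["condition"]]).strip() if "condition" in cols else "",
            )
        )
    return records


def parse_pathogenesis(
    path: PathLike,
    synonyms: Optional[dict[str, tuple[str, ...]]] = None,
) -> list[PathogenesisAnnotation]:
    """Parse per-target GOF/LOF annotations; conflicting directions are an input error."""
    df = read_table(path)
    cols = _resolve_columns(
        df, required=["target", "direction"], optional=["description", "provenance"],
        synonyms=synonyms, path=path,
    )
    by_target: dict[str, PathogenesisAnnotation] = {}
    for _, row in df.iterrows():
        target = harmonize_symbol(str(row[cols["target"]]))
        try:
            direction = Direction(str(row[cols["direction"]]).strip().upper())
        except ValueError as exc:
            raise InputDataError(f"{path}: bad direction for {target}: {exc}") from exc
        ann = PathogenesisAnnotation(
            target=target,
            direction=direction,
            description=str(row[cols["description"]]).strip() if "description" in cols else "",
            provenance=str(row[cols["provenance"]]).strip() if "provenance" in cols else "",
        )
        prior = by_target.get(target)
        if prior is not None and prior.direction is not ann.direction:
            raise InputDataError(
                f"{path}: conflicting GOF/LOF directions for target {target}"
            )
        by_target.setdefault(target, ann)
    return list(by_target.values())


# ---------------------------------------------------------------------------
# Writers (full-fidelity, so that write -> parse round-trips exactly)
# ---------------------------------------------------------------------------

def write_evidence_records(records: Iterable[EvidenceRecord], path: PathLike) -> None:
    rows = [
        {
            "gene": r.gene,
            "source": r.source.value,
            "trait": r.trait or "",
            "p_value": "" if r.p_value is None else repr(r.p_value),
            "snp": r.snp_id or "",
            "metabolite": r.metabolite or "",
            "role": r.role.value if r.role else "",
            "citation": r.citation or "",
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["gene", "source", "trait", "p_value", "snp", "metabolite", "role", "citation"],
    ).to_csv(path, sep="\t", index=False)


def read_evidence_records(path: PathLike) -> list[EvidenceRecord]:
    df = read_table(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            EvidenceRecord(
                gene=row["gene"],
                source=Source(row["source"]),
                trait=row["trait"] or None,
                p_value=float(row["p_value"]) if row["p_value"] else None,
                snp_id=row["snp"] or None,
                metabolite=row["metabolite"] or None,
                role=Role(row["role"]) if row["role"] else None,
                citation=row["citation"] or None,
            )
        )
    return records


def write_metabolite_table(assocs: Iterable[MetaboliteAssociation], path: PathLike) -> None:
    pd.DataFrame(
        [{"metabolite": a.metabolite, "protein": a.protein, "role": a.role.value} for a in assocs],
        columns=["metabolite", "protein", "role"],
    ).to_csv(path, sep="\t", index=False)


def write_drug_targets(records: Iterable[DrugTargetRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "drug": r.drug,
                "drug_id": r.drug_id,
                "group": r.group.value,
                "target": r.target,
                "target_category": r.target_category.value,
                "actions": ";".join(sorted(a.value for a in r.actions)),
                "indication": r.indication,
            }
            for r in records
        ],
        columns=["drug", "drug_id", "group", "target", "target_category", "actions", "indication"],
    ).to_csv(path, sep="\t", index=False)


def write_trials(records: Iterable[TrialRecord], path: PathLike) -> None:
    pd.DataFrame(
        [{"drug": r.drug, "stage": r.stage, "condition": r.condition} for r in records],
        columns=["drug", "stage", "condition"],
    ).to_csv(path, sep="\t", index=False)


def write_pathogenesis(records: Iterable[PathogenesisAnnotation], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "target": r.target,
                "direction": r.direction.value,
                "description": r.description,
                "provenance": r.provenance,
            }
            for r in records
        ],
        columns=["target", "direction", "description", "provenance"],
    ).to_csv(path, sep="\t", index=False)


def write_rejects_report(rejects: Iterable[RejectedRow], path: PathLike) -> None:
    pd.DataFrame(
        [{"path": r.path, "row": r.row_index, "reason": r.reason} for r in rejects],
        columns=["path", "row", "reason"],
    ).to_csv(path, sep="\t", index=False)
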