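"""Shared domain types for the melanoma drug-repurposing pipeline.

The pipeline passes evidence about disease-gene associations (from GWAS,
PheWAS, metabolomics, transcriptomics and biomedical/OMIM-style sources)
through a cascade that maps genes to approved drugs, removes drugs already
indicated for melanoma, filters on pathogenesis/action concordance, and
finally scores candidates against connectivity-map expression signatures.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Source(str, enum.Enum):
    """Evidence source an association was drawn from."""

    GWAS = "GWAS"
    PHEWAS = "PHEWAS"
    METABOLOMICS = "METABOLOMICS"
    TRANSCRIPTOMICS = "TRANSCRIPTOMICS"
    BIOMEDICAL = "BIOMEDICAL"


#: Sources for which a per-record p-value is meaningful.
P_VALUE_SOURCES = frozenset({Source.GWAS, Source.PHEWAS})


class Role(str, enum.Enum):
    """Functional role of a protein in a metabolite association."""

    ENZYME = "ENZYME"
    TRANSPORTER = "TRANSPORTER"
    UNKNOWN = "UNKNOWN"


class DrugGroup(str, enum.Enum):
    """Regulatory/approval group of a drug."""

    APPROVED = "APPROVED"
    EXPERIMENTAL = "EXPERIMENTAL"
    ILLICIT = "ILLICIT"
    WITHDRAWN = "WITHDRAWN"
    INVESTIGATIONAL = "INVESTIGATIONAL"
    NUTRACEUTICAL = "NUTRACEUTICAL"


class TargetCategory(str, enum.Enum):
    PROTEIN = "PROTEIN"
    ENZYME = "ENZYME"
    TRANSPORTER = "TRANSPORTER"
    CARRIER = "CARRIER"


class Action(str, enum.Enum):
    """Mechanistic relation of a drug to one of its targets."""

    INHIBITOR = "INHIBITOR"
    ANTAGONIST = "ANTAGONIST"
    BLOCKER = "BLOCKER"
    AGONIST = "AGONIST"
    INDUCER = "INDUCER"
    ACTIVATOR = "ACTIVATOR"
    SUBSTRATE = "SUBSTRATE"
    BINDER = "BINDER"
    UNKNOWN = "UNKNOWN"


#: Actions that reduce target activity.
LOWERING_ACTIONS = frozenset({Action.INHIBITOR, Action.ANTAGONIST, Action.BLOCKER})
#: Actions that raise target activity.
RAISING_ACTIONS = frozenset({Action.AGONIST, Action.INDUCER, Action.ACTIVATOR})
#: Actions with no defined direction of effect.
NEUTRAL_ACTIONS = frozenset({Action.SUBSTRATE, Action.BINDER, Action.UNKNOWN})


class Direction(str, enum.Enum):
    """Pathogenic direction of a gene's contribution to disease."""

    GOF = "GOF"
    LOF = "LOF"


class Verdict(str, enum.Enum):
    """Concordance of a drug action with a target's pathogenic direction."""

    CONCORDANT = "CONCORDANT"
    NEUTRAL = "NEUTRAL"
    DISCORDANT = "DISCORDANT"


class Policy(str, enum.Enum):
    STRICT = "STRICT"
    LENIENT = "LENIENT"


def harmonize_symbol(raw: str, alias_map: Optional[dict[str, str]] = None) -> str:
    """Normalize a gene/protein symbol: strip whitespace, uppercase, apply aliases.

    No live nomenclature lookup is performed; an optional user-supplied alias
    map handles known synonym collisions.
    """
    sym = raw.strip().upper()
    if alias_map:
        sym = alias_map.get(sym, sym)
    return sym


@dataclass(frozen=True)
class EvidenceRecord:
    """One gene-disease association from one evidence source."""

    gene: str
    source: Source
    trait: Optional[str] = None
    p_value: Optional[float] = None
    snp_id: Optional[str] = None
    metabolite: Optional[str] = None
    role: Optional[Role] = None
    citation: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene or self.gene != self.gene.strip().upper():
            raise ValueError(f"gene symbol not harmonized: {self.gene!r}")
        if self.p_value is not None and self.source not in P_VALUE_SOURCES:
            raise ValueError(f"p_value given for {self.source.value} record")
        if self.source is not Source.METABOLOMICS and (
            self.metabolite is not None or self.role is not None
        ):
            raise ValueError("metabolite/role only valid for METABOLOMICS records")


@dataclass(frozen=True)
class MetaboliteAssociation:
    """A metabolite linked to a protein acting as enzyme/transporter."""

    metabolite: str
    protein: str
    role: Role = Role.UNKNOWN


@dataclass(frozen=True)
class DrugTargetRecord:
    """One drug-target link from a DrugBank-style table."""

    drug: str
    drug_id: str
    group: DrugGroup
    target: str
    target_category: TargetCategory
    actions: frozenset[Action]
    indication: str = ""

    def __post_init__(self) -> None:
        if not self.actions:
            raise ValueError(f"actions empty for {self.drug}/{self.target}")


@dataclass(frozen=True)
class PathogenesisAnnotation:
    """Per-target gain/loss-of-function direction with free-text description."""

    target: str
    direction: Direction
    description: str = ""
    provenance: str = ""


@dataclass(frozen=True)
class TrialRecord:
    """A drug known to be in a disease-related clinical trial."""

    drug: str
    stage: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.drug:
            raise ValueError("trial drug name is empty")


@dataclass
class TargetAssessment:
    """One target of a candidate drug with its concordance verdict."""

    target: str
    target_category: TargetCategory
    actions: frozenset[Action]
    verdict: Optional[Verdict] = None  # None until pathogenesis stage runs


@dataclass
class TraceEntry:
    stage: str
    decision: str  # RETAINED | REJECTED
    reason: str = ""


@dataclass
class CandidateDrug:
    """A drug surviving (or rejected by) the repurposing cascade, with audit trail."""

    drug: str
    drug_id: str
    targets: list[TargetAssessment] = field(default_factory=list)
    filter_trace: list[TraceEntry] = field(default_factory=list)

    def rejected(self) -> bool:
        return any(t.decision == "REJECTED" for t in self.filter_trace)
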