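"""The drug-repurposing cascade: mapping, known-indication exclusion, concordance.

Three stages, each shrinking the candidate set and writing an audit trail:

1. ``map_drugs`` — intersect a disease gene/protein set with a DrugBank-style
   drug-target table, keeping approved drugs with at least one in-set target.
2. ``exclude_known`` — drop drugs already in disease-related clinical trials
   (name-level matching, case- and punctuation-insensitive).
3. ``pathogenesis_filter`` — keep drugs whose action on at least one
   annotated target is concordant (or neutral) with that target's pathogenic
   direction: inhibition of a gain-of-function gene, activation of a
   loss-of-function gene.  Substrate/binder/unknown actions carry no
   direction and are neutral.

Every drug entering a stage leaves with a trace entry recording the decision
and reason, so the full cascade is auditable.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .types import (
    Action,
    CandidateDrug,
    Direction,
    DrugGroup,
    DrugTargetRecord,
    LOWERING_ACTIONS,
    NEUTRAL_ACTIONS,
    PathogenesisAnnotation,
    Policy,
    RAISING_ACTIONS,
    TargetAssessment,
    TraceEntry,
    TrialRecord,
    Verdict,
)

PathLike = Union[str, Path]

STAGE_MAPPING = "DRUG_MAPPING"
STAGE_EXCLUSION = "INDICATION_EXCLUSION"
STAGE_PATHOGENESIS = "PATHOGENESIS_FILTER"


def map_drugs(
    gene_set: Iterable[str],
    drug_targets: Iterable[DrugTargetRecord],
    groups_allowed: frozenset[DrugGroup] = frozenset({DrugGroup.APPROVED}),
) -> tuple[list[CandidateDrug], int]:
    """Map the disease gene set onto druggable targets.

    Returns one CandidateDrug per drug (in allowed groups) with at least one
    target inside ``gene_set`` — target lists restricted to in-set targets —
    plus the count of distinct targets mapped.
    """
    genes = set(gene_set)
    by_drug: dict[tuple[str, str], CandidateDrug] = {}
    mapped_targets: set[str] = set()
    for rec in drug_targets:
        if rec.group not in groups_allowed or rec.target not in genes:
            continue
        key = (rec.drug, rec.drug_id)
        cand = by_drug.get(key)
        if cand is None:
            cand = CandidateDrug(drug=rec.drug, drug_id=rec.drug_id)
            cand.filter_trace.append(
                TraceEntry(STAGE_MAPPING, "RETAINED", "target in disease gene set")
            )
            by_drug[key] = cand
        cand.targets.append(
            TargetAssessment(
                target=rec.target,
                target_category=rec.target_category,
                actions=rec.actions,
            )
        )
        mapped_targets.add(rec.target)
    candidates = sorted(by_drug.values(), key=lambda c: (c.drug, c.drug_id))
    return candidates, len(mapped_targets)


_PUNCT = re.compile(r"[^a-z0-9]+")


def normalize_drug_name(name: str) -> str:
    """Case-fold and strip punctuation/whitespace for name-level drug matching."""
    return _PUNCT.sub("", name.lower())


def exclude_known(
    candidates: Iterable[CandidateDrug],
    trials: Iterable[TrialRecord],
) -> tuple[list[CandidateDrug], int]:
    """Remove candidates already under trial for the disease.

    Returns the retained candidates and the overlap count.  Excluded drugs
    get a REJECTED trace entry; retained ones a RETAINED entry.
    """
    trial_names = {normalize_drug_name(t.drug) for t in trials}
    retained: list[CandidateDrug] = []
    overlap = 0
    for cand in candidates:
        if normalize_drug_name(cand.drug) in trial_names:
            overlap += 1
            cand.filter_trace.append(
                TraceEntry(STAGE_EXCLUSION, "REJECTED", "known disease indication (trial list)")
            )
        else:
            cand.filter_trace.append(
                TraceEntry(STAGE_EXCLUSION, "RETAINED", "not in trial list")
            )
            retained.append(cand)
    return retained, overlap


def concordance(
    direction: Direction,
    action: Action,
    policy: Policy = Policy.STRICT,
    sibling_actions: Optional[frozenset[Action]] = None,
) -> Verdict:
    """Concordance verdict for one (pathogenic direction, drug action) pair.

    STRICT: lowering actions (inhibitor/antagonist/blocker) are concordant
    with GOF targets, raising actions (agonist/inducer/activator) with LOF
    targets; substrate/binder/unknown are neutral; everything else is
    discordant.  LENIENT additionally downgrades a discordant verdict to
    neutral when the same target also carries a neutral action
    (``sibling_actions``), reflecting that mixed-mode entries are not
    direction-breaking.
    """
    if action in NEUTRAL_ACTIONS:
        return Verdict.NEUTRAL
    concordant = (
        action in LOWERING_ACTIONS
        if direction is Direction.GOF
        else action in RAISING_ACTIONS
    )
    if concordant:
        return Verdict.CONCORDANT
    if policy is Policy.LENIENT and sibling_actions and (sibling_actions & NEUTRAL_ACTIONS):
        return Verdict.NEUTRAL
    return Verdict.DISCORDANT


def _target_verdict(
    assessment: TargetAssessment, direction: Direction, policy: Policy
) -> Verdict:
    """Best verdict over a target's actions (CONCORDANT > NEUTRAL > DISCORDANT)."""
    order = {Verdict.CONCORDANT: 0, Verdict.NEUTRAL: 1, Verdict.DISCORDANT: 2}
    verdicts = [
        concordance(direction, a, policy, sibling_actions=assessment.actions)
        for a in assessment.actions
    ]
    return min(verdicts, key=order.__getitem__)


def pathogenesis_filter(
    candidates: Iterable[CandidateDrug],
    annotations: Iterable[PathogenesisAnnotation],
    policy: Policy = Policy.STRICT,
) -> list[CandidateDrug]:
    """Keep drugs with >= 1 annotated target whose verdict is concordant or neutral.

    Targets without a GOF/LOF annotation are dropped from consideration; a
    drug left with no annotated target is rejected with reason NO_ANNOTATION.
    Verdicts are recorded on each annotated TargetAssessment.
    """
    directions = {a.target: a.direction for a in annotations}
    retained: list[CandidateDrug] = []
    for cand in candidates:
        annotated = [t for t in cand.targets if t.target in directions]
        if not annotated:
            cand.filter_trace.append(
                TraceEntry(STAGE_PATHOGENESIS, "REJECTED", "NO_ANNOTATION")
            )
            continue
        keep = False
        for t in annotated:
            t.verdict = _target_verdict(t, directions[t.target], policy)
            if t.verdict in (Verdict.CONCORDANT, Verdict.NEUTRAL):
                keep = True
        if keep:
            cand.filter_trace.append(
                TraceEntry(STAGE_PATHOGENESIS, "RETAINED", "concordant/neutral annotated target")
            )
            retained.append(cand)
        else:
            cand.filter_trace.append(
                TraceEntry(STAGE_PATHOGENESIS, "REJECTED", "all annotated targets discordant")
            )
    return retained


def surviving_targets(
    candidates: Iterable[CandidateDrug], annotations: Iterable[PathogenesisAnnotation]
) -> set[str]:
    """Distinct annotated targets carried by the retained drugs."""
    directions = {a.target: a.direction for a in annotations}
    out: set[str] = set()
    for cand in candidates:
        for t in cand.targets:
            if t.target in directions and t.verdict in (Verdict.CONCORDANT, Verdict.NEUTRAL):
                out.add(t.target)
    return out


def write_trace(candidates: Iterable[CandidateDrug], path: PathLike) -> None:
    """Write the per-drug filter audit log as TSV."""
    rows = []
    for cand in candidates:
        for entry in cand.filter_trace:
            rows.append(
                {
                    "drug": cand.drug,
                    "drug_id": cand.drug_id,
                    "stage": entry.stage,
                    "decision": entry.decision,
                    "reason": entry.reason,
                }
            )
    pd.DataFrame(rows, columns=["drug", "drug_id", "stage", "decision", "reason"]).to_csv(
        path, sep="\t", index=False
    )
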