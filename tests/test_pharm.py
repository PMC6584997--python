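"""Drug mapping, known-indication exclusion and GOF/LOF concordance filtering."""

import pytest
from hypothesis import given, settings, strategies as st

from melanoseek.pharm import (
    concordance,
    exclude_known,
    map_drugs,
    normalize_drug_name,
    pathogenesis_filter,
    surviving_targets,
)
from melanoseek.types import (
    Action,
    CandidateDrug,
    Direction,
    DrugGroup,
    DrugTargetRecord,
    PathogenesisAnnotation,
    Policy,
    TargetAssessment,
    TargetCategory,
    TrialRecord,
    Verdict,
)


def dt(drug, target, group=DrugGroup.APPROVED, actions=(Action.INHIBITOR,)):
    return DrugTargetRecord(
        drug=drug, drug_id=f"DB_{drug}", group=group, target=target,
        target_category=TargetCategory.ENZYME, actions=frozenset(actions),
    )


def cand(drug, *targets):
    return CandidateDrug(
        drug=drug, drug_id=f"DB_{drug}",
        targets=[
            TargetAssessment(
                target=t, target_category=TargetCategory.ENZYME, actions=frozenset(a)
            )
            for t, a in targets
        ],
    )


def test_map_drugs_group_and_set_filter():
    records = [
        dt("Milrinone", "PDE3A"),
        dt("DrugX", "PDE3A", group=DrugGroup.EXPERIMENTAL),
        dt("DrugY", "NOTINSET"),
    ]
    candidates, n_targets = map_drugs({"PDE3A"}, records)
    assert [c.drug for c in candidates] == ["Milrinone"]
    assert n_targets == 1
    assert map_drugs(set(), records) == ([], 0)


def test_map_drugs_restricts_target_list():
    records = [dt("D", "A"), dt("D", "B"), dt("D", "OUT")]
    candidates, n_targets = map_drugs({"A", "B"}, records)
    assert sorted(t.target for t in candidates[0].targets) == ["A", "B"]
    assert n_targets == 2


def test_exclude_known_name_normalization():
    candidates = [cand("Drug-A", ("T", [Action.INHIBITOR])),
                  cand("drug b", ("T", [Action.INHIBITOR])),
                  cand("DrugC", ("T", [Action.INHIBITOR]))]
    trials = [TrialRecord(drug="DRUG A."), TrialRecord(drug="Drug_B")]
    retained, overlap = exclude_known(candidates, trials)
    assert [c.drug for c in retained] == ["DrugC"]
    assert overlap == 2
    rejected = [c for c in candidates if c.rejected()]
    assert {c.drug for c in rejected} == {"Drug-A", "drug b"}
    assert all(
        e.stage == "INDICATION_EXCLUSION" for c in rejected for e in c.filter_trace
        if e.decision == "REJECTED"
    )


def test_exclude_known_empty_trials():
    candidates = [cand("A", ("T", [Action.INHIBITOR]))]
    retained, overlap = exclude_known(candidates, [])
    assert len(retained) == 1 and overlap == 0


def test_normalize_drug_name():
    assert normalize_drug_name("  Acetyl-Salicylic Acid ") == "acetylsalicylicacid"


# Hand-written STRICT truth table over the full direction x action product.
STRICT_TRUTH = {
    (Direction.GOF, Action.INHIBITOR): Verdict.CONCORDANT,
    (Direction.GOF, Action.ANTAGONIST): Verdict.CONCORDANT,
    (Direction.GOF, Action.BLOCKER): Verdict.CONCORDANT,
    (Direction.GOF, Action.AGONIST): Verdict.DISCORDANT,
    (Direction.GOF, Action.INDUCER): Verdict.DISCORDANT,
    (Direction.GOF, Action.ACTIVATOR): Verdict.DISCORDANT,
    (Direction.GOF, Action.SUBSTRATE): Verdict.NEUTRAL,
    (Direction.GOF, Action.BINDER): Verdict.NEUTRAL,
    (Direction.GOF, Action.UNKNOWN): Verdict.NEUTRAL,
    (Direction.LOF, Action.INHIBITOR): Verdict.DISCORDANT,
    (Direction.LOF, Action.ANTAGONIST): Verdict.DISCORDANT,
    (Direction.LOF, Action.BLOCKER): Verdict.DISCORDANT,
    (Direction.LOF, Action.AGONIST): Verdict.CONCORDANT,
    (Direction.LOF, Action.INDUCER): Verdict.CONCORDANT,
    (Direction.LOF, Action.ACTIVATOR): Verdict.CONCORDANT,
    (Direction.LOF, Action.SUBSTRATE): Verdict.NEUTRAL,
    (Direction.LOF, Action.BINDER): Verdict.NEUTRAL,
    (Direction.LOF, Action.UNKNOWN): Verdict.NEUTRAL,
}


@pytest.mark.parametrize("direction,action", list(STRICT_TRUTH))
def test_concordance_strict_truth_table(direction, action):
    assert concordance(direction, action, Policy.STRICT) == STRICT_TRUTH[(direction, action)]


def test_concordance_lenient_downgrade():
    # a discordant action on a target that also carries a neutral action
    sib = frozenset({Action.INHIBITOR, Action.SUBSTRATE})
    assert concordance(Direction.LOF, Action.INHIBITOR, Policy.LENIENT, sib) == Verdict.NEUTRAL
    # without a neutral sibling the verdict stays discordant
    assert (
        concordance(Direction.LOF, Action.INHIBITOR, Policy.LENIENT, frozenset({Action.INHIBITOR}))
        == Verdict.DISCORDANT
    )


def test_pathogenesis_filter_rules():
    annotations = [
        PathogenesisAnnotation(target="G1", direction=Direction.GOF),
        PathogenesisAnnotation(target="G2", direction=Direction.GOF),
    ]
    keep = cand("Keep", ("G1", [Action.INHIBITOR]))
    drop = cand("Drop", ("G1", [Action.AGONIST]))
    unannot = cand("NoAnn", ("OTHER", [Action.INHIBITOR]))
    mixed = cand("Mixed", ("G1", [Action.AGONIST]), ("G2", [Action.INHIBITOR]))
    retained = pathogenesis_filter([keep, drop, unannot, mixed], annotations)
    assert [c.drug for c in retained] == ["Keep", "Mixed"]
    assert any(
        e.reason == "NO_ANNOTATION" for e in unannot.filter_trace if e.decision == "REJECTED"
    )
    assert surviving_targets(retained, annotations) == {"G1", "G2"}


def test_pathogenesis_filter_all_discordant_retains_none():
    annotations = [PathogenesisAnnotation(target="G", direction=Direction.LOF)]
    drugs = [cand(f"D{i}", ("G", [Action.INHIBITOR])) for i in range(5)]
    assert pathogenesis_filter(drugs, annotations) == []


def test_unannotated_targets_ignored_for_verdict():
    # judged on annotated targets only: the unannotated discordant-looking
    # target must not rescue or sink the drug
    annotations = [PathogenesisAnnotation(target="G", direction=Direction.GOF)]
    c = cand("D", ("G", [Action.AGONIST]), ("H", [Action.INHIBITOR]))
    assert pathogenesis_filter([c], annotations) == []


# --- fuzzed cascade invariants ---------------------------------------------

drug_names = st.text(alphabet="abcdXYZ", min_size=1, max_size=4)
gene_names = st.sampled_from(["G1", "G2", "G3", "G4"])


@st.composite
def cascade_inputs(draw):
    records = draw(
        st.lists(
            st.builds(
                dt,
                drug=drug_names,
                target=gene_names,
                group=st.sampled_from(list(DrugGroup)),
                actions=st.frozensets(st.sampled_from(list(Action)), min_size=1, max_size=3),
            ),
            max_size=25,
        )
    )
    gene_set = draw(st.frozensets(gene_names, max_size=4))
    trials = draw(st.lists(st.builds(TrialRecord, drug=drug_names), max_size=8))
    annotations = [
        PathogenesisAnnotation(target=g, direction=d)
        for g, d in draw(
            st.dictionaries(gene_names, st.sampled_from(list(Direction)), max_size=4)
        ).items()
    ]
    return records, gene_set, trials, annotations


@settings(max_examples=200, deadline=None, derandomize=True)
@given(cascade_inputs())
def test_cascade_monotone_and_trace_complete(inputs):
    """Each stage's retained set is a subset of its input; every drug is
    accounted for as retained or rejected-with-reason."""
    records, gene_set, trials, annotations = inputs
    mapped, _ = map_drugs(gene_set, records)
    retained, overlap = exclude_known(mapped, trials)
    assert len(retained) + overlap == len(mapped)
    assert {c.drug for c in retained} <= {c.drug for c in mapped}
    surviving = pathogenesis_filter(retained, annotations)
    assert {c.drug for c in surviving} <= {c.drug for c in retained}
    for c in mapped:
        final = [e for e in c.filter_trace if e.decision == "REJECTED"]
        if c in surviving:
            assert not final
        else:
            assert len(final) == 1 and final[0].reason
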