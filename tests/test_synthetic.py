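"""Determinism, planted structure and recoverability of the fixture generator."""

import dataclasses
import filecmp
from pathlib import Path

import pytest

from melanoseek.connectivity import aggregate_drugs, connectivity_scores, select_candidates
from melanoseek.evidence_io import (
    parse_gene_list,
    parse_gwas_evidence,
    parse_metabolite_table,
    parse_phewas_evidence,
)
from melanoseek.integration import build_profiles, multi_source_total, venn_counts
from melanoseek.synthetic import (
    ANCHORS_NEG,
    ANCHORS_POS,
    SyntheticConfig,
    SyntheticConfigError,
    generate_all,
    generate_signatures,
    plan_gene_memberships,
)
from melanoseek.types import Source

from conftest import small_config


def tree_files(root):
    return sorted(p.relative_to(root) for p in Path(root).rglob("*") if p.is_file())


def test_byte_identical_regeneration(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    generate_all(small_config(seed=3), a)
    generate_all(small_config(seed=3), b)
    files = tree_files(a)
    assert files == tree_files(b)
    for rel in files:
        assert filecmp.cmp(a / rel, b / rel, shallow=False), rel


def test_different_seed_changes_output(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    generate_all(small_config(seed=3), a)
    generate_all(small_config(seed=4), b)
    assert not filecmp.cmp(a / "evidence" / "gwas.tsv", b / "evidence" / "gwas.tsv",
                           shallow=False)


def test_generated_files_parse_cleanly_with_planted_counts(small_fixture, small_cfg):
    fixture_dir, truth = small_fixture
    evid = fixture_dir / "evidence"
    rejects = []
    gwas = parse_gwas_evidence(evid / "gwas.tsv", rejects=rejects)
    phewas = parse_phewas_evidence(evid / "phewas.tsv", rejects=rejects)
    _, met = parse_metabolite_table(evid / "metabolites.tsv")
    trans = parse_gene_list(evid / "transcriptome.txt", Source.TRANSCRIPTOMICS)
    biomed = parse_gene_list(evid / "biomedical.txt", Source.BIOMEDICAL)
    assert rejects == []
    sizes = small_cfg.source_sizes
    assert len({r.gene for r in gwas}) == sizes[Source.GWAS]
    assert len({r.gene for r in phewas}) == sizes[Source.PHEWAS]
    assert len(met) == sizes[Source.METABOLOMICS]
    assert len(trans) == sizes[Source.TRANSCRIPTOMICS]
    assert len(biomed) == sizes[Source.BIOMEDICAL]
    profiles = build_profiles(gwas + phewas + met + trans + biomed)
    counts = venn_counts(profiles)
    assert len(profiles) == truth["evidence"]["union_size"]
    assert multi_source_total(counts) == small_cfg.multi_source_overlap


def test_planted_p_value_ranges(small_fixture, small_cfg):
    fixture_dir, _ = small_fixture
    gwas = parse_gwas_evidence(fixture_dir / "evidence" / "gwas.tsv")
    lo, hi = small_cfg.gwas_p_range
    ps = [r.p_value for r in gwas]
    assert min(ps) == pytest.approx(lo) and max(ps) == pytest.approx(hi)
    assert all(lo <= p <= hi for p in ps)
    phewas = parse_phewas_evidence(fixture_dir / "evidence" / "phewas.tsv")
    plo, phi = small_cfg.phewas_p_range
    pps = [r.p_value for r in phewas]
    assert min(pps) == pytest.approx(plo) and max(pps) == pytest.approx(phi)


def test_zero_overlap_plants_disjoint_sources():
    cfg = small_config()
    cfg.multi_source_overlap = 0
    memberships = plan_gene_memberships(cfg)
    assert all(len(combo) == 1 for combo in memberships.values())


def test_infeasible_configs_rejected():
    cfg = small_config()
    cfg.multi_source_overlap = 10**6
    with pytest.raises(SyntheticConfigError):
        cfg.validate()
    cfg2 = small_config()
    cfg2.concentration = 0.0
    with pytest.raises(SyntheticConfigError, match="concentration"):
        cfg2.validate()
    cfg3 = small_config()
    cfg3.n_survivor_drugs = cfg3.n_mapped_drugs
    with pytest.raises(SyntheticConfigError):
        cfg3.validate()


def score_panel(signatures, tags):
    scores = connectivity_scores(tags, signatures)
    return aggregate_drugs(scores, {s.instance_id: s.drug for s in signatures})


def test_inactive_drugs_center_near_zero():
    cfg = dataclasses.replace(
        small_config(seed=5),
        n_survivor_drugs=8, n_cmap_active=2, n_cmap_missing=0, n_cmap_inactive=4,
        n_annotated_targets=4, instances_per_drug=20,
    )
    signatures, tags, truth = generate_signatures(cfg)
    results = score_panel(signatures, tags)
    for drug in truth["inactive"]:
        assert results[drug].n_instances == 20
        assert abs(results[drug].mean) < 0.15


def test_high_concentration_drives_active_scores_to_one():
    cfg = dataclasses.replace(
        small_config(seed=5),
        n_survivor_drugs=6, n_cmap_active=3, n_cmap_missing=0, n_annotated_targets=4,
        concentration=50.0,
    )
    signatures, tags, truth = generate_signatures(cfg)
    results = score_panel(signatures, tags)
    for drug in truth["active"]:
        assert results[drug].mean > 0.99
    for drug in truth["reversed"]:
        assert results[drug].mean < -0.99


def test_planted_actives_recovered_with_high_sensitivity(small_fixture):
    fixture_dir, truth = small_fixture
    import json

    detail = json.loads((fixture_dir / "truth_detail.json").read_text())["cmap"]
    from melanoseek.connectivity import read_signature_panel, read_tagset

    panel = read_signature_panel(fixture_dir / "signatures" / "manifest.tsv")
    tags = read_tagset(fixture_dir / "signatures" / "tags.gmt")
    results = score_panel(panel, tags)
    sel = select_candidates(
        results, list(ANCHORS_POS), list(ANCHORS_NEG),
        candidates=detail["active"] + detail["reversed"] + detail["not_in_cmap"],
    )
    retained = {r.drug for r in sel.retained}
    active = set(detail["active"])
    assert len(retained & active) / len(active) >= 0.9
    assert not retained & set(detail["reversed"])
    assert sorted(sel.not_in_cmap) == detail["not_in_cmap"]
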