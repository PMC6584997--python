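"""KS enrichment against a brute-force oracle; connectivity scoring and selection."""

import numpy as np
import pytest

from melanoseek.connectivity import (
    ConnectivityResult,
    RankedSignature,
    TagSet,
    aggregate_drugs,
    connectivity_scores,
    ks_enrichment,
    ks_enrichment_positions,
    raw_connectivity,
    read_gmt,
    read_rnk,
    read_tagset,
    scale_scores,
    select_candidates,
    write_gmt,
    write_rnk,
)


def brute_es(positions, n):
    """Independent oracle: explicit evaluation of the two running maxima."""
    V = sorted(positions)
    t = len(V)
    a = max(j / t - V[j - 1] / n for j in range(1, t + 1))
    b = max(V[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


def sig(genes, instance="i1", drug="d1"):
    return RankedSignature(instance_id=instance, drug=drug, cell_line="MCF7",
                           ranking=tuple(genes))


def universe(n):
    return [f"g{i}" for i in range(n)]


def test_hand_evaluated_examples():
    assert ks_enrichment_positions([1, 2], 10) == pytest.approx(0.8)
    assert ks_enrichment_positions([9, 10], 10) == pytest.approx(-0.9)


def test_all_genes_tagged_matches_oracle():
    for n in (2, 3, 10, 17):
        assert ks_enrichment_positions(list(range(1, n + 1)), n) == pytest.approx(
            brute_es(range(1, n + 1), n)
        )


def test_matches_bruteforce_on_random_cases():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(2, 51))
        t = int(rng.integers(1, n + 1))
        pos = sorted(int(p) + 1 for p in rng.choice(n, size=t, replace=False))
        es = ks_enrichment_positions(pos, n)
        assert es == brute_es(pos, n)
        assert -1.0 <= es <= 1.0


def test_reversal_of_top_concentration_mirrors_exactly():
    """A positive (top-concentrated) score reverses to exactly -ES - 1/n:
    the running maxima swap roles on the reversed rank grid, shifted by one
    rank cell.  (Sets piled at *both* ends score negative in either
    orientation, so a blanket sign-negation law cannot hold.)"""
    rng = np.random.default_rng(7)
    checked = 0
    for _ in range(600):
        n = int(rng.integers(2, 51))
        t = int(rng.integers(1, n + 1))
        pos = sorted(int(p) + 1 for p in rng.choice(n, size=t, replace=False))
        es = ks_enrichment_positions(pos, n)
        rev = sorted(n + 1 - p for p in pos)
        es_rev = ks_enrichment_positions(rev, n)
        if es > 0:
            assert es_rev == pytest.approx(-es - 1.0 / n)
            checked += 1
    assert checked > 100  # the positive branch was actually exercised


def test_shifting_a_tag_toward_top_never_decreases_es():
    rng = np.random.default_rng(11)
    for _ in range(300):
        n = int(rng.integers(3, 40))
        t = int(rng.integers(1, n))
        pos = sorted(int(p) + 1 for p in rng.choice(n, size=t, replace=False))
        free = sorted(set(range(1, n + 1)) - set(pos))
        moved = None
        for p in reversed(pos):
            lower = [f for f in free if f < p]
            if lower:
                moved = sorted(set(pos) - {p} | {lower[-1]})
                break
        if moved is None:
            continue
        assert ks_enrichment_positions(moved, n) >= ks_enrichment_positions(pos, n) - 1e-12


def test_gene_interface_and_errors():
    s = sig(universe(10))
    assert ks_enrichment(["g0", "g1"], s) == pytest.approx(0.8)
    with pytest.raises(KeyError, match="NOT_THERE"):
        ks_enrichment(["NOT_THERE"], s)
    assert ks_enrichment(["g0", "NOT_THERE"], s, skip_missing=True) == pytest.approx(
        ks_enrichment(["g0"], s)
    )
    with pytest.raises(ValueError):
        ks_enrichment([], s)


def test_tagset_validation():
    with pytest.raises(ValueError):
        TagSet(up=frozenset({"a"}), down=frozenset({"a"}))
    with pytest.raises(ValueError):
        TagSet()


def test_raw_connectivity_sign_rules():
    genes = universe(10)
    s = sig(genes)
    # up at top, down at bottom: opposite signs, strongly positive raw
    tags = TagSet(up=frozenset(genes[:2]), down=frozenset(genes[-2:]))
    assert raw_connectivity(tags, s) == pytest.approx(0.8 - (-0.9))
    # both at top: same sign -> 0
    tags_same = TagSet(up=frozenset(genes[:2]), down=frozenset(genes[2:4]))
    assert raw_connectivity(tags_same, s) == 0.0
    # single-sided fallback: up tags at the bottom give a negative score
    tags_up_only = TagSet(up=frozenset(genes[-2:]))
    assert raw_connectivity(tags_up_only, s) < 0


def test_batch_scaling_extremes_exact():
    raws = {"a": 1.7, "b": 0.85, "c": -0.4, "d": -1.6, "e": 0.0}
    scaled = scale_scores(raws)
    assert scaled["a"] == 1.0 and scaled["d"] == -1.0
    assert scaled["b"] == pytest.approx(0.5)
    assert scaled["c"] == pytest.approx(-0.25)
    assert scaled["e"] == 0.0
    assert all(-1.0 <= v <= 1.0 for v in scaled.values())


def test_connectivity_scores_extremal_instances_hit_unity():
    genes = universe(20)
    tags = TagSet(up=frozenset(genes[:3]), down=frozenset(genes[-3:]))
    best = sig(genes, "best", "dpos")                      # up top, down bottom
    worst = sig(list(reversed(genes)), "worst", "dneg")    # reversed
    mild = sig(genes[5:] + genes[:5], "mild", "dmid")
    scores = connectivity_scores(tags, [best, worst, mild])
    assert scores["best"] == 1.0
    assert scores["worst"] == -1.0


def test_aggregate_mean_and_enrichment():
    scores = {f"i{k}": s for k, s in enumerate([0.9, 0.8, 0.7, 0.1, -0.2, -0.5])}
    drugs = {"i0": "top", "i1": "top", "i2": "top", "i3": "x", "i4": "x", "i5": "x"}
    res = aggregate_drugs(scores, drugs)
    assert res["top"].mean == pytest.approx((0.9 + 0.8 + 0.7) / 3)
    assert res["x"].n_instances == 3
    # the drug occupying the top 3 of 6 instances: positive enrichment equal
    # to the brute-force KS on its positions
    assert res["top"].enrichment == pytest.approx(brute_es([1, 2, 3], 6))
    assert res["top"].enrichment > 0
    single = aggregate_drugs({"i": 0.4}, {"i": "only"})
    assert single["only"].mean == pytest.approx(0.4)
    two = aggregate_drugs({"a": 0.5, "b": -0.5}, {"a": "d", "b": "d"})
    assert two["d"].mean == 0.0


def make_results(means):
    return {
        drug: ConnectivityResult(drug=drug, instance_scores={f"{drug}_1": m}, mean=m)
        for drug, m in means.items()
    }


def test_select_candidates_rules():
    results = make_results(
        {"pos_anchor": 0.6, "neg_anchor": -0.4, "good": 0.3, "bad": -0.2, "weak": 0.05}
    )
    sel = select_candidates(results, ["pos_anchor"], ["neg_anchor"], min_abs_mean=0.1)
    assert [r.drug for r in sel.retained] == ["good"]
    assert {r.drug for r in sel.rejected} == {"bad", "weak"}


def test_select_candidates_not_in_cmap_and_order_invariance():
    results = make_results({"p": 0.5, "n": -0.5, "a": 0.2, "b": -0.1})
    sel = select_candidates(results, ["p"], ["n"], candidates=["a", "b", "ghost"])
    assert sel.not_in_cmap == ["ghost"]
    assert [r.drug for r in sel.retained] == ["a"]
    # invariance to candidate input ordering
    sel2 = select_candidates(results, ["p"], ["n"], candidates=["ghost", "b", "a"])
    assert [r.drug for r in sel2.retained] == [r.drug for r in sel.retained]


def test_select_candidates_errors():
    results = make_results({"p": 0.5, "q": 0.4})
    with pytest.raises(ValueError, match="anchors_pos"):
        select_candidates(results, [])
    with pytest.raises(KeyError, match="ghost"):
        select_candidates(results, ["ghost"])
    with pytest.raises(ValueError, match="conflicting"):
        select_candidates(results, ["p"], ["q"])  # both anchors positive


def test_rnk_and_gmt_round_trip(tmp_path):
    s = sig(universe(8), "inst", "drug")
    write_rnk(s, tmp_path / "inst.rnk")
    back = read_rnk(tmp_path / "inst.rnk", "inst", "drug", "MCF7")
    assert back.ranking == s.ranking
    write_gmt({"up": {"g1", "g0"}, "down": {"g7"}}, tmp_path / "tags.gmt")
    sets = read_gmt(tmp_path / "tags.gmt")
    assert sets["up"] == frozenset({"g0", "g1"})
    tags = read_tagset(tmp_path / "tags.gmt")
    assert tags.down == frozenset({"g7"})


def test_ranking_must_be_permutation():
    with pytest.raises(ValueError, match="permutation"):
        sig(["a", "a", "b"])
    with pytest.raises(ValueError, match="universe"):
        sig(["a"])
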