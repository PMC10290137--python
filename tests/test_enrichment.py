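"""Over-representation analysis: GMT parsing, Fisher/hypergeometric oracle
agreement, BH adjustment and hierarchy rollup."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epinet import simulate
from epinet.enrichment import (
    GeneSetCollection,
    count_rollup_nodes,
    enrich,
    hierarchy_rollup,
    read_gmt,
    read_hierarchy,
)
from epinet.errors import ConfigError, FormatError, StructuralError


def hypergeom_upper_tail(n_bg, n_query, n_set, k):
    """Over-representation p by direct summation:
    sum_{i>=k} C(n_set, i) C(n_bg-n_set, n_query-i) / C(n_bg, n_query)."""
    total = comb(n_bg, n_query)
    s = 0
    for i in range(k, min(n_set, n_query) + 1):
        if n_query - i <= n_bg - n_set:
            s += comb(n_set, i) * comb(n_bg - n_set, n_query - i)
    return s / total


def bh_reference(pvals):
    """Ten-line step-up Benjamini-Hochberg, independent of statsmodels."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# GMT parsing


def test_gmt_duplicate_members_collapsed(tmp_path):
    p = tmp_path / "s.gmt"
    p.write_text("S\tdesc\tA\tB\tA\n")
    coll = read_gmt(p)
    assert coll.sets["S"] == {"A", "B"}


def test_gmt_empty_file(tmp_path):
    p = tmp_path / "e.gmt"
    p.write_text("")
    assert len(read_gmt(p)) == 0


def test_gmt_short_line_is_format_error_with_line_number(tmp_path):
    p = tmp_path / "bad.gmt"
    p.write_text("S1\tdesc\tA\nS2\tonly-two-fields\n")
    with pytest.raises(FormatError, match="line 2"):
        read_gmt(p)


def test_gmt_empty_sets_go_to_report(tmp_path):
    p = tmp_path / "s.gmt"
    p.write_text("S1\tdesc\tA\nS2\tdesc\t\t\n")
    coll = read_gmt(p)
    assert "S2" not in coll.sets and coll.rejected == ["S2"]


def test_gmt_sizes_match_generator_ground_truth(tmp_path, ppi_fixture):
    _, paths, truth = ppi_fixture
    coll = read_gmt(paths["gmt"])
    assert coll.sets[truth.planted_enriched_set] == truth.planted_set_members


# ---------------------------------------------------------------------------
# enrichment


def test_set_equal_to_background_p_one():
    bg = {f"g{i}" for i in range(30)}
    coll = GeneSetCollection(sets={"ALL": frozenset(bg)})
    res = enrich({"g0", "g1", "g2"}, coll, bg)
    assert res.loc[0, "p_value"] == pytest.approx(1.0)


def test_fisher_p_equals_direct_hypergeometric_summation():
    """background 100, query 10, set 20, overlap 8: p equals the direct
    hypergeometric sum."""
    bg = {f"g{i}" for i in range(100)}
    members = frozenset(f"g{i}" for i in range(20))
    # query: 8 members inside the set, 2 outside
    query = {f"g{i}" for i in range(8)} | {"g90", "g91"}
    coll = GeneSetCollection(sets={"S": members})
    res = enrich(query, coll, bg)
    expect = hypergeom_upper_tail(100, 10, 20, 8)
    assert res.loc[0, "overlap"] == 8
    assert res.loc[0, "p_value"] == pytest.approx(expect, rel=1e-10)
    assert res.loc[0, "entities_ratio"] == pytest.approx(0.2)
    assert res.loc[0, "found_ratio"] == pytest.approx(0.8)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    n_bg=st.integers(5, 60),
    data=st.data(),
)
def test_fisher_matches_hypergeometric_property(n_bg, data):
    n_set = data.draw(st.integers(1, n_bg))
    n_query = data.draw(st.integers(1, n_bg))
    k_max = min(n_set, n_query)
    k_min = max(0, n_set + n_query - n_bg)
    k = data.draw(st.integers(k_min, k_max))
    bg = {f"g{i}" for i in range(n_bg)}
    members = frozenset(f"g{i}" for i in range(n_set))
    query = {f"g{i}" for i in range(k)} | {
        f"g{n_set + i}" for i in range(n_query - k)
    }
    coll = GeneSetCollection(sets={"S": members})
    res = enrich(query, coll, bg)
    expect = hypergeom_upper_tail(n_bg, n_query, n_set, k)
    assert res.loc[0, "p_value"] == pytest.approx(expect, rel=1e-9)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
def test_bh_matches_reference_step_up(pvals):
    from statsmodels.stats.multitest import multipletests

    got = multipletests(np.asarray(pvals), method="fdr_bh")[1]
    np.testing.assert_allclose(got, bh_reference(pvals), rtol=1e-12, atol=1e-15)


def test_fdr_at_least_p_after_monotonicity():
    bg = {f"g{i}" for i in range(50)}
    coll = GeneSetCollection(sets={
        f"S{j}": frozenset(f"g{i}" for i in range(j, j + 10)) for j in range(5)
    })
    res = enrich({f"g{i}" for i in range(12)}, coll, bg)
    assert (res["fdr"] >= res["p_value"] - 1e-15).all()


def test_planted_set_attains_minimum_fdr(ppi_fixture):
    _, paths, truth = ppi_fixture
    coll = read_gmt(paths["gmt"])
    query = set(truth.planted_set_members)
    res = enrich(query, coll)
    assert res.loc[0, "set_name"] == truth.planted_enriched_set
    assert res.loc[0, "fdr"] == res["fdr"].min()


def test_enrich_invariant_to_input_order():
    bg = {f"g{i}" for i in range(40)}
    sets = {
        "X": frozenset(["g1", "g2", "g3"]),
        "Y": frozenset(["g4", "g5", "g6", "g7"]),
    }
    res1 = enrich({"g1", "g2", "g4"}, GeneSetCollection(sets=dict(sets)), bg)
    res2 = enrich({"g4", "g2", "g1"}, GeneSetCollection(
        sets=dict(reversed(list(sets.items())))), bg)
    assert res1.to_dict() == res2.to_dict()


def test_query_outside_background_dropped_with_warning():
    bg = {"a", "b", "c", "d"}
    coll = GeneSetCollection(sets={"S": frozenset(["a", "b"])})
    with pytest.warns(UserWarning, match="outside the background"):
        res = enrich({"a", "zzz"}, coll, bg)
    assert res.loc[0, "query_size"] == 1


def test_empty_background_is_argument_error():
    with pytest.raises(ConfigError):
        enrich(set(), GeneSetCollection(), set())


# ---------------------------------------------------------------------------
# hierarchy rollup


def _results(coll, query, bg):
    return enrich(query, coll, bg)


def test_flat_collection_gives_one_level_tree():
    bg = {f"g{i}" for i in range(20)}
    coll = GeneSetCollection(sets={"A": frozenset(["g1"]), "B": frozenset(["g2"])})
    tree = hierarchy_rollup(_results(coll, {"g1"}, bg), coll)
    assert {t["name"] for t in tree} == {"A", "B"}
    assert all(t["children"] == [] for t in tree)


def test_borderless_parent_with_enriched_child():
    bg = {f"g{i}" for i in range(20)}
    coll = GeneSetCollection(
        sets={"parent": frozenset(["g10"]), "child": frozenset(["g1", "g2"])},
        hierarchy=[("parent", "child")],
    )
    tree = hierarchy_rollup(_results(coll, {"g1", "g2"}, bg), coll)
    (root,) = tree
    assert root["name"] == "parent" and root["empty"] is True
    (child,) = root["children"]
    assert child["name"] == "child" and child["empty"] is False
    assert child["overlap"] == 2


def test_rollup_node_count_equals_hierarchy_node_count():
    bg = {f"g{i}" for i in range(30)}
    sets = {f"S{i}": frozenset([f"g{i}"]) for i in range(6)}
    hierarchy = [("S0", "S1"), ("S0", "S2"), ("S2", "S3"), ("S4", "S5")]
    coll = GeneSetCollection(sets=sets, hierarchy=hierarchy)
    tree = hierarchy_rollup(_results(coll, {"g1", "g3"}, bg), coll)
    assert count_rollup_nodes(tree) == 6


def test_cycle_raises_structural_error():
    coll = GeneSetCollection(
        sets={"A": frozenset(["x"]), "B": frozenset(["y"])},
        hierarchy=[("A", "B"), ("B", "A")],
    )
    res = enrich({"x"}, coll, {"x", "y"})
    with pytest.raises(StructuralError, match="cycle"):
        hierarchy_rollup(res, coll)


def test_hierarchy_reader(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text("parent\tchild\nA\tB\nA\tC\n")
    assert read_hierarchy(p) == [("A", "B"), ("A", "C")]
    bad = tmp_path / "bad.tsv"
    bad.write_text("A\n")
    with pytest.raises(FormatError, match="line 1"):
        read_hierarchy(bad)
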