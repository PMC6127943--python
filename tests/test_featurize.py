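"""Feature-space construction and binary vector extraction."""

import numpy as np
import pytest

from kgscreen import (
    Combination,
    KGPathFeaturizer,
    KnowledgeGraph,
    ProteinSet,
    Triple,
    ValidationError,
    build_feature_space,
    extract_features,
    extract_matrix,
    restrict_to_sources,
)
from kgscreen.featurize import FeatureId

from conftest import random_combo, random_graph


def combo(dt, dp, cid="c"):
    return Combination(cid, ProteinSet(frozenset(dt), "DT"),
                       ProteinSet(frozenset(dp), "DP"))


def two_pred_one_src_graph():
    return KnowledgeGraph([
        Triple("A", "binds", "B", frozenset(("S1",))),
        Triple("B", "activates", "C", frozenset(("S1",))),
    ])


# ---------------------------------------------------------------------------
# Space construction
# ---------------------------------------------------------------------------

def test_baseline_always_three_flags(scenario_fx):
    for g in (scenario_fx.graph, two_pred_one_src_graph()):
        spec = build_feature_space(g, "baseline")
        assert len(spec) == 3
        assert all(f.kind == "flag" for f in spec.features)


def test_full_space_size_formula():
    # 1 overlap flag + 4 value slots x (2 predicates + 1 source)
    spec = build_feature_space(two_pred_one_src_graph(), "full")
    assert len(spec) == 1 + 4 * (2 + 1) == 13


def test_indirect_only_space_drops_non_indirect_slots():
    spec = build_feature_space(two_pred_one_src_graph(), "indirect_only")
    assert len(spec) == 2 * 3 == 6
    assert {f.slot for f in spec.features} == {"DTIP", "IPDP"}


def test_reference_scale_vocabularies_give_281_features():
    triples = []
    # one hub edge per predicate / source so vocabularies reach 45 and 25
    for i in range(45):
        triples.append(Triple("H", f"P{i:02d}", f"N{i}",
                              frozenset((f"S{i % 25:02d}",))))
    g = KnowledgeGraph(triples)
    assert len(build_feature_space(g, "full")) == 1 + 4 * (45 + 25) == 281


def test_unknown_variant_rejected(scenario_fx):
    with pytest.raises(ValidationError):
        build_feature_space(scenario_fx.graph, "everything")


def test_spec_ordering_is_deterministic(scenario_fx):
    a = build_feature_space(scenario_fx.graph, "full")
    b = build_feature_space(scenario_fx.graph, "full")
    assert a == b
    keys = [f.sort_key for f in a.features]
    assert keys == sorted(keys)


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def test_pathless_combo_gives_all_zero_vector(scenario_fx):
    v = extract_features(combo("G", "A", "c"), scenario_fx.graph,
                         build_feature_space(scenario_fx.graph, "full"))
    assert set(v.bits) == {0}


def test_single_direct_triple_sets_exactly_its_two_bits(scenario_fx):
    spec = build_feature_space(scenario_fx.graph, "full")
    v = extract_features(combo("B", "C"), scenario_fx.graph, spec)
    on = {str(spec.features[i]) for i, b in enumerate(v.bits) if b}
    assert on == {"DIRECT:predicate:binds", "DIRECT:provenance:S2"}


def test_overlap_self_relationship_bits(scenario_fx):
    spec = build_feature_space(scenario_fx.graph, "full")
    v = extract_features(combo("A", "A"), scenario_fx.graph, spec)
    on = {str(spec.features[i]) for i, b in enumerate(v.bits) if b}
    assert on == {
        "OVERLAP_FLAG:flag:",
        "SELF:predicate:homodimerizes",
        "SELF:provenance:S1",
    }


def brute_feature_set(c, graph):
    """Independent oracle: slot/value sets straight from triple scans."""
    from test_pathfind import brute_direct, brute_indirect, brute_overlap, _joins

    on = set()
    shared = brute_overlap(c, graph)
    if shared:
        on.add("OVERLAP_FLAG:flag:")
        for p in shared:
            for t in _joins(graph.triples, p, p):
                on.add(f"SELF:predicate:{t.predicate}")
                on.update(f"SELF:provenance:{s}" for s in t.provenance)
    direct = brute_direct(c, graph)
    if direct:
        on.add("COOC_DIRECT:flag:")
        for dt, dp in direct:
            for t in _joins(graph.triples, dt, dp):
                on.add(f"DIRECT:predicate:{t.predicate}")
                on.update(f"DIRECT:provenance:{s}" for s in t.provenance)
    indirect = brute_indirect(c, graph)
    if indirect:
        on.add("COOC_INDIRECT:flag:")
        for dt, ip, dp in indirect:
            for t in _joins(graph.triples, dt, ip):
                on.add(f"DTIP:predicate:{t.predicate}")
                on.update(f"DTIP:provenance:{s}" for s in t.provenance)
            for t in _joins(graph.triples, ip, dp):
                on.add(f"IPDP:predicate:{t.predicate}")
                on.update(f"IPDP:provenance:{s}" for s in t.provenance)
    return on


@pytest.mark.parametrize("trial", range(10))
def test_vectors_match_bruteforce_path_oracle(trial):
    rng = np.random.default_rng([600, trial])
    g = random_graph(rng, n_nodes=30, n_edges=70, self_loop_prob=0.1)
    c = random_combo(rng, g, dt_size=3, dp_size=4)
    spec = build_feature_space(g, "full")
    v = extract_features(c, g, spec)
    on = {str(spec.features[i]) for i, b in enumerate(v.bits) if b}
    oracle = brute_feature_set(c, g)
    # the full variant carries no co-occurrence flag columns
    oracle -= {"COOC_DIRECT:flag:", "COOC_INDIRECT:flag:"}
    assert on == oracle


@pytest.mark.parametrize("variant", ["predicate", "provenance", "indirect_only"])
def test_variant_vectors_are_projections_of_full(variant, rng):
    g = random_graph(rng, n_nodes=20, n_edges=50)
    combos = [random_combo(rng, g, combo_id=f"c{i}") for i in range(8)]
    full_spec = build_feature_space(g, "full")
    full = extract_matrix(combos, g, full_spec)
    sub_spec = build_feature_space(g, variant)
    sub = extract_matrix(combos, g, sub_spec)
    col = {f: i for i, f in enumerate(full_spec.features)}
    for j, f in enumerate(sub_spec.features):
        if f.kind == "flag" and f.slot != "OVERLAP_FLAG":
            continue  # co-occurrence flags exist only in the baseline space
        assert np.array_equal(sub[:, j], full[:, col[f]]), str(f)


def test_cooc_flags_consistent_with_value_bits(rng):
    # baseline flags agree with the OR over the full variant's slot columns
    g = random_graph(rng, n_nodes=20, n_edges=50, self_loop_prob=0.15)
    combos = [random_combo(rng, g, combo_id=f"c{i}") for i in range(10)]
    base = extract_matrix(combos, g, build_feature_space(g, "baseline"))
    full_spec = build_feature_space(g, "full")
    full = extract_matrix(combos, g, full_spec)
    direct_cols = [i for i, f in enumerate(full_spec.features) if f.slot == "DIRECT"]
    indirect_cols = [i for i, f in enumerate(full_spec.features)
                     if f.slot in ("DTIP", "IPDP")]
    self_cols = [i for i, f in enumerate(full_spec.features) if f.slot == "SELF"]
    overlap_col = [i for i, f in enumerate(full_spec.features)
                   if f.slot == "OVERLAP_FLAG"][0]
    assert np.array_equal(base[:, 1], full[:, direct_cols].max(axis=1))
    assert np.array_equal(base[:, 2], full[:, indirect_cols].max(axis=1))
    # any SELF bit implies the overlap flag
    assert np.all(full[:, self_cols].max(axis=1) <= full[:, overlap_col])


def test_adding_a_triple_only_flips_bits_upward(rng):
    g = random_graph(rng, n_nodes=15, n_edges=30)
    c = random_combo(rng, g)
    spec = build_feature_space(g, "full")
    before = extract_features(c, g, spec).bits
    nodes = sorted(g.proteins)
    g2 = KnowledgeGraph(
        list(g.triples) + [Triple(nodes[0], "binds", nodes[1], frozenset(("S1",)))],
        proteins=g.proteins,
    )
    after = extract_features(c, g2, spec).bits
    assert all(b >= a for a, b in zip(before, after))


def test_spec_graph_vocabulary_mismatch_rejected(scenario_fx):
    spec = build_feature_space(scenario_fx.graph, "full")
    other = two_pred_one_src_graph()
    with pytest.raises(ValidationError):
        extract_features(combo("A", "B"), other, spec)


def test_featurizer_is_sklearn_compatible(scenario_fx):
    feat = KGPathFeaturizer(graph=scenario_fx.graph, variant="full")
    assert feat.get_params()["variant"] == "full"
    feat.set_params(variant="baseline").fit()
    X = feat.transform(list(scenario_fx.combos))
    assert X.shape == (3, 3)
    assert list(feat.get_feature_names_out()) == list(feat.spec_.names)


# ---------------------------------------------------------------------------
# Source restriction
# ---------------------------------------------------------------------------

def test_excluding_absent_source_only_drops_its_columns():
    g = KnowledgeGraph(
        [Triple("A", "binds", "B", frozenset(("S1",)))],
        source_vocabulary=("S1", "S2"),
    )
    c = combo("A", "B")
    spec = build_feature_space(g, "full")
    new_spec, vectors, _ = restrict_to_sources(spec, [c], g, "S2")
    dropped = set(spec.names) - set(new_spec.names)
    assert dropped == {f"{slot}:provenance:S2" for slot in ("SELF", "DIRECT", "DTIP", "IPDP")}
    old = extract_features(c, g, spec)
    kept_idx = [i for i, f in enumerate(spec.features) if str(f) in set(new_spec.names)]
    assert tuple(old.bits[i] for i in kept_idx) == vectors[0].bits


def test_excluding_sole_source_removes_predicate_support():
    g = KnowledgeGraph([Triple("A", "binds", "B", frozenset(("S1",)))])
    c = combo("A", "B")
    spec = build_feature_space(g, "full")
    new_spec, vectors, _ = restrict_to_sources(spec, [c], g, "S1")
    # both the provenance columns of S1 and the now-unsupported binds columns go
    assert not any("provenance:S1" in n or "predicate:binds" in n for n in new_spec.names)
    assert all(b == 0 for b in vectors[0].bits)


@pytest.mark.parametrize("trial", range(5))
def test_restriction_equals_pipeline_on_filtered_graph(trial):
    rng = np.random.default_rng([601, trial])
    g = random_graph(rng, n_nodes=20, n_edges=45)
    combos = [random_combo(rng, g, combo_id=f"c{i}") for i in range(6)]
    spec = build_feature_space(g, "full")
    new_spec, vectors, _ = restrict_to_sources(spec, combos, g, "S1")
    # oracle: delete sole-source triples by hand and re-run the full pipeline
    kept_triples = [t for t in g.triples if t.provenance != frozenset(("S1",))]
    g2 = KnowledgeGraph(kept_triples, proteins=g.proteins,
                        predicate_vocabulary=g.predicate_vocabulary,
                        source_vocabulary=g.source_vocabulary)
    oracle = extract_matrix(combos, g2, new_spec)
    assert np.array_equal(np.array([v.bits for v in vectors]), oracle)


def test_unknown_source_rejected(scenario_fx):
    spec = build_feature_space(scenario_fx.graph, "full")
    with pytest.raises(ValidationError):
        restrict_to_sources(spec, [], scenario_fx.graph, "NOPE")
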