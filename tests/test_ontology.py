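"""Ontology propagation and parent-child overrepresentation tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from genepriority.ontology import (
    OntologyDAG,
    bonferroni_select,
    cross_species_overlap,
    map_to_phenotype_terms,
    n_testable_terms,
    parent_child_test,
    propagate,
)

from conftest import random_dag_instance


# ---------------------------------------------------------------------------
# DAG basics and propagation


def test_cycle_rejected():
    with pytest.raises(ValueError):
        OntologyDAG.from_edges(["a", "b"], [("a", "b"), ("b", "a")])


def test_propagation_closes_a_chain():
    dag = OntologyDAG.from_edges(["root", "A", "B"], [("A", "root"), ("B", "A")])
    ann = propagate(dag, {"g1": {"B"}})
    assert ann.propagated["g1"] == {"B", "A", "root"}
    assert ann.direct["g1"] == {"B"}


def test_propagation_empty_direct_set():
    dag = OntologyDAG.from_edges(["root"], [])
    ann = propagate(dag, {"g1": set()})
    assert ann.propagated["g1"] == frozenset()


def test_propagation_unknown_term_fatal():
    dag = OntologyDAG.from_edges(["root"], [])
    with pytest.raises(ValueError, match="nope"):
        propagate(dag, {"g1": {"nope"}})


def test_propagation_matches_transitive_closure_oracle():
    """Propagation equals a brute-force repeated-parent-lookup closure."""
    rng = np.random.default_rng(42)
    for _ in range(5):
        dag, genes, direct = random_dag_instance(rng, n_terms=15, n_genes=50)
        ann = propagate(dag, direct)
        for g, ts in direct.items():
            closed = set(ts)
            while True:
                grown = set(closed)
                for t in closed:
                    grown |= dag.parents(t)
                if grown == closed:
                    break
                closed = grown
            assert ann.propagated[g] == closed


def test_propagated_closed_under_parents(small_bundle):
    dag = small_bundle.ontology_human
    ann = propagate(dag, small_bundle.annotations_human)
    for g, terms in list(ann.propagated.items())[:50]:
        for t in terms:
            assert dag.parents(t) <= terms


# ---------------------------------------------------------------------------
# parent-child test


def _two_level(universe, parent_genes, child_genes):
    dag = OntologyDAG.from_edges(
        ["root", "parent", "child"], [("parent", "root"), ("child", "parent")]
    )
    direct = {}
    for g in parent_genes:
        direct.setdefault(g, set()).add("child" if g in child_genes else "parent")
    return dag, propagate(dag, direct)


def test_term_equal_to_parent_gives_p_one():
    """K = M: every draw from the parent set is annotated, so P(X >= k) = 1."""
    universe = [f"g{i}" for i in range(10)]
    dag, ann = _two_level(universe, universe[:6], universe[:6])
    res = {r.term: r for r in parent_child_test(universe[:3], universe, dag, ann)}
    assert res["child"].K == res["child"].M
    assert res["child"].p_value == pytest.approx(1.0)


def test_study_covering_parents_gives_p_one():
    """m = M: the study saturates the parent population."""
    universe = [f"g{i}" for i in range(10)]
    dag, ann = _two_level(universe, universe[:4], universe[:2])
    res = {r.term: r for r in parent_child_test(universe[:4], universe, dag, ann)}
    assert res["child"].m == res["child"].M
    assert res["child"].p_value == pytest.approx(1.0)


def test_parent_child_matches_exhaustive_enumeration():
    """p for the worked 10-gene instance equals exhaustive subset counting.

    Parent annotates g1..g8, child g1..g4.  With study {g1,g2,g3,g9} only
    m = 3 study genes fall inside the M = 8 parent genes and k = 3 hit the
    K = 4 child genes; enumerating all C(8,3) parent subsets gives the
    exact null probability of X >= 3, which is 1/14.  With study
    {g1,g2,g3,g5} the fourth study gene also lies in the parent set
    (m = 4) and enumeration over C(8,4) subsets gives 17/70.
    """
    universe = [f"g{i}" for i in range(1, 11)]
    parent_genes = [f"g{i}" for i in range(1, 9)]
    child_genes = [f"g{i}" for i in range(1, 5)]
    child_set = set(child_genes)

    def enumerate_tail(m, k):
        hits = sum(
            1
            for subset in itertools.combinations(parent_genes, m)
            if len(child_set & set(subset)) >= k
        )
        return hits / len(list(itertools.combinations(parent_genes, m)))

    dag, ann = _two_level(universe, parent_genes, child_genes)

    res = {r.term: r for r in parent_child_test(["g1", "g2", "g3", "g9"], universe, dag, ann)}
    r = res["child"]
    assert (r.M, r.K, r.m, r.k) == (8, 4, 3, 3)
    assert r.p_value == pytest.approx(enumerate_tail(3, 3)) == pytest.approx(1 / 14)

    res = {r.term: r for r in parent_child_test(["g1", "g2", "g3", "g5"], universe, dag, ann)}
    r = res["child"]
    assert (r.M, r.K, r.m, r.k) == (8, 4, 4, 3)
    assert r.p_value == pytest.approx(enumerate_tail(4, 3)) == pytest.approx(17 / 70)


def test_flat_ontology_equals_classic_hypergeometric():
    """With every term a child of the root and every gene annotated,
    conditioning on the parent is conditioning on the universe, i.e. the
    classic one-sided test."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        n_genes = int(rng.integers(20, 60))
        genes = [f"g{i}" for i in range(n_genes)]
        terms = ["root"] + [f"t{i}" for i in range(5)]
        dag = OntologyDAG.from_edges(terms, [(t, "root") for t in terms[1:]])
        direct = {}
        for g in genes:
            ts = frozenset(t for t in terms[1:] if rng.random() < 0.3)
            # annotate everything so the root's gene set is the universe
            direct[g] = ts if ts else frozenset({terms[1 + int(rng.integers(5))]})
        ann = propagate(dag, direct)
        study = [g for g in genes if rng.random() < 0.3]
        term_genes = {
            t: {g for g, ts in ann.propagated.items() if t in ts} for t in terms
        }
        for r in parent_child_test(study, genes, dag, ann):
            if r.term == "root":
                continue
            M = n_genes
            K = len(term_genes[r.term])
            m = len(study)
            k = len(set(study) & term_genes[r.term])
            assert r.p_value == pytest.approx(float(hypergeom.sf(k - 1, M, K, m)))


def test_p_monotone_in_study_hits():
    """Adding a study gene annotated to the term (counts otherwise fixed)
    never increases the p-value."""
    for k in range(0, 4):
        p_hi = float(hypergeom.sf(k - 1, 20, 8, 6))
        p_lo = float(hypergeom.sf(k, 20, 8, 6))
        assert p_lo <= p_hi + 1e-12


def test_p_distribution_conservative_under_random_study():
    """Under uniformly random study sets the p-value at a fixed term is
    stochastically >= Uniform(0,1)."""
    rng = np.random.default_rng(5)
    universe = [f"g{i}" for i in range(40)]
    dag, ann = _two_level(universe, universe[:25], universe[:10])
    pvals = []
    for _ in range(400):
        study = list(rng.choice(universe, size=12, replace=False))
        res = {r.term: r for r in parent_child_test(study, universe, dag, ann)}
        pvals.append(res["child"].p_value if "child" in res else 1.0)
    pvals = np.array(pvals)
    for alpha in (0.05, 0.1, 0.25, 0.5):
        # binomial slack: 3 sd at n = 400
        assert (pvals <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 400)


def test_study_outside_universe_fatal():
    universe = ["g1", "g2"]
    dag, ann = _two_level(universe, universe, universe[:1])
    with pytest.raises(ValueError):
        parent_child_test(["gX"], universe, dag, ann)


# ---------------------------------------------------------------------------
# Bonferroni selection


def test_bonferroni_threshold_is_alpha_over_n():
    from genepriority.ontology import EnrichmentResult

    results = [
        EnrichmentResult(f"t{i}", 1, 1, 1, 10, p_value=p)
        for i, p in enumerate([4e-4, 5e-4, 6e-4] + [0.5] * 97)
    ]
    sel = bonferroni_select(results, alpha=0.05)
    assert sel == {"t0", "t1"}  # threshold 0.05/100 = 5e-4, boundary inclusive


def test_bonferroni_single_boundary_inclusive():
    from genepriority.ontology import EnrichmentResult

    r = EnrichmentResult("t", 1, 1, 1, 10, p_value=0.05)
    assert bonferroni_select([r], alpha=0.05) == {"t"}
    assert r.significant


def test_bonferroni_all_ones_and_empty():
    from genepriority.ontology import EnrichmentResult

    results = [EnrichmentResult(f"t{i}", 1, 1, 1, 10, p_value=1.0) for i in range(5)]
    assert bonferroni_select(results, 0.05) == frozenset()
    assert bonferroni_select([], 0.05) == frozenset()


# ---------------------------------------------------------------------------
# cross-species overlap and phenotype mapping


def test_overlap_is_intersection():
    assert cross_species_overlap({"A", "B", "C"}, {"B", "C", "D"}) == {"B", "C"}
    assert cross_species_overlap({"A"}, {"B"}) == frozenset()


def test_overlap_recovers_planted_terms():
    """At default effect sizes the planted enriched terms survive both
    species' Bonferroni selections and their intersection."""
    from genepriority import RunConfig, run_pipeline
    from genepriority.simulate import ScenarioConfig, generate_bundle

    recovered = 0
    n_seeds = 3
    for seed in range(n_seeds):
        cfg = ScenarioConfig(seed=seed)
        bundle = generate_bundle(cfg)
        report = run_pipeline(bundle, RunConfig(n_random_sets=50), seed=seed)
        # the generator writes the planted enriched terms as the first
        # n_enriched_terms cross-ontology records
        planted_sources = set(bundle.xmap["source_term"][: cfg.n_enriched_terms])
        if planted_sources <= report.overlap_terms:
            recovered += 1
    assert recovered == n_seeds


def test_phenotype_mapping_rolls_up_to_top_level():
    # root with tops A,B,C; A has children a1, a2; a2 has child a3
    dag = OntologyDAG.from_edges(
        ["root", "A", "B", "C", "a1", "a2", "a3"],
        [("A", "root"), ("B", "root"), ("C", "root"),
         ("a1", "A"), ("a2", "A"), ("a3", "a2")],
    )
    xmap = pd.DataFrame(
        {
            "source_term": ["go1", "go2", "go3", "go4"],
            "target_term": ["a1", "a3", "B", "C"],
            "distance": [1, 1, 1, 2],
        }
    )
    mp_terms, top = map_to_phenotype_terms({"go1", "go2", "go3", "go4"}, xmap, dag)
    assert mp_terms == {"a1", "a3", "B"}          # distance-2 record ignored
    assert top == {"A", "B"}                      # B is its own rollup

    mp_terms, top = map_to_phenotype_terms(set(), xmap, dag)
    assert mp_terms == frozenset() and top == frozenset()


def test_phenotype_mapping_seven_terms_three_top_levels():
    """Seven mapped phenotype terms spread over three branches roll up to
    exactly three top-level terms."""
    terms = ["root", "G", "N", "E", "g1", "g2", "g3", "n1", "n2", "e1", "e2"]
    edges = [("G", "root"), ("N", "root"), ("E", "root"),
             ("g1", "G"), ("g2", "G"), ("g3", "g2"),
             ("n1", "N"), ("n2", "n1"), ("e1", "E"), ("e2", "e1")]
    dag = OntologyDAG.from_edges(terms, edges)
    targets = ["g1", "g2", "g3", "n1", "n2", "e1", "e2"]
    xmap = pd.DataFrame(
        {
            "source_term": [f"go{i}" for i in range(7)],
            "target_term": targets,
            "distance": [1] * 7,
        }
    )
    mp_terms, top = map_to_phenotype_terms({f"go{i}" for i in range(7)}, xmap, dag)
    assert len(mp_terms) == 7
    assert top == {"G", "N", "E"}


def test_phenotype_mapping_unknown_term_fatal():
    dag = OntologyDAG.from_edges(["root", "A"], [("A", "root")])
    xmap = pd.DataFrame(
        {"source_term": ["go1"], "target_term": ["missing"], "distance": [1]}
    )
    with pytest.raises(ValueError, match="missing"):
        map_to_phenotype_terms({"go1"}, xmap, dag)
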