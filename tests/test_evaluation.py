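"""Resnik profile similarity, reclassification AUC, facet composition."""

import numpy as np
import pytest

from phemine.evaluation import (
    PhenotypeProfile,
    category_proportions,
    facet_expression,
    facet_inclusion,
    ic_from_profiles,
    profile_similarity,
    reclassification_auc,
    term_similarity,
)
from phemine.ontology import OntologyClass, OntologyGraph


@pytest.fixture
def two_branch():
    """root -> {A -> {A1, A2}, B -> {B1}} with hand-assignable IC."""
    classes = [OntologyClass(x) for x in ["R", "A", "B", "A1", "A2", "B1"]]
    edges = [("A", "R"), ("B", "R"), ("A1", "A"), ("A2", "A"), ("B1", "B")]
    return OntologyGraph(classes, edges)


IC = {"R": 0.0, "A": 0.4, "B": 0.5, "A1": 0.9, "A2": 1.0, "B1": 0.8}


class TestProfileSimilarity:
    def test_self_similarity_is_term_ic(self, two_branch):
        p = PhenotypeProfile("D", frozenset({"A1"}))
        assert profile_similarity(p, p, IC, two_branch) == pytest.approx(IC["A1"])

    def test_disjoint_branches_share_only_root(self, two_branch):
        a = PhenotypeProfile("D", frozenset({"A1"}))
        b = PhenotypeProfile("E", frozenset({"B1"}))
        assert profile_similarity(a, b, IC, two_branch) == 0.0

    def test_bma_matches_hand_computed_matrix(self, two_branch):
        a = PhenotypeProfile("D", frozenset({"A1", "A2", "B1"}))
        b = PhenotypeProfile("E", frozenset({"A1", "B"}))
        # pairwise Resnik matrix (rows A1,A2,B1 x cols A1,B):
        #   A1: sim(A1,A1)=0.9  sim(A1,B)=0.0
        #   A2: sim(A2,A1)=0.4  sim(A2,B)=0.0
        #   B1: sim(B1,A1)=0.0  sim(B1,B)=0.5
        row_best = np.mean([0.9, 0.4, 0.5])
        col_best = np.mean([0.9, 0.5])
        expected = (row_best + col_best) / 2
        assert profile_similarity(a, b, IC, two_branch) == pytest.approx(expected)
        # mean of all pairs
        expected_avg = np.mean([0.9, 0.0, 0.4, 0.0, 0.0, 0.5])
        assert profile_similarity(a, b, IC, two_branch, "avg_pairwise") == pytest.approx(
            expected_avg
        )

    def test_symmetry_and_bound(self, two_branch):
        a = PhenotypeProfile("D", frozenset({"A1", "B1"}))
        b = PhenotypeProfile("E", frozenset({"A2"}))
        s1 = profile_similarity(a, b, IC, two_branch)
        s2 = profile_similarity(b, a, IC, two_branch)
        assert s1 == pytest.approx(s2)
        assert s1 <= max(IC.values())

    def test_empty_profile_rejected(self, two_branch):
        a = PhenotypeProfile("D", frozenset({"A1"}))
        with pytest.raises(ValueError):
            profile_similarity(a, PhenotypeProfile("E", frozenset()), IC, two_branch)

    def test_ic_from_profiles_propagates_usage(self, two_branch):
        profiles = [
            PhenotypeProfile("D", frozenset({"A1"})),
            PhenotypeProfile("E", frozenset({"A2"})),
        ]
        ic = ic_from_profiles(profiles, two_branch, normalize=False)
        assert ic["R"] == 0.0
        assert ic["A"] == 0.0  # both annotations propagate through A
        assert ic["A1"] == pytest.approx(np.log(2))


def _disjoint_profiles(n, prefix, g_classes):
    return [
        PhenotypeProfile(f"DIS:{i}", frozenset({f"{prefix}:{i}"})) for i in range(n)
    ]


class TestReclassificationAUC:
    def _star_ontology(self, n):
        classes = [OntologyClass("R")] + [OntologyClass(f"L:{i}") for i in range(n)]
        edges = [(f"L:{i}", "R") for i in range(n)]
        return OntologyGraph(classes, edges)

    def test_identical_disjoint_profiles_give_auc_one(self):
        g = self._star_ontology(6)
        profiles = [PhenotypeProfile(f"DIS:{i}", frozenset({f"L:{i}"})) for i in range(6)]
        res = reclassification_auc(profiles, profiles, {p.disease: p.disease for p in profiles}, g=g, n_boot=200, seed=0)
        assert res.auc == 1.0
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.n_diseases == 6

    def test_all_tied_similarities_give_half(self):
        g = self._star_ontology(4)
        # every profile identical: every pairwise similarity equal
        profiles = [PhenotypeProfile(f"DIS:{i}", frozenset({"L:0"})) for i in range(4)]
        res = reclassification_auc(profiles, profiles, {p.disease: p.disease for p in profiles}, g=g, n_boot=50, seed=0)
        assert res.auc == pytest.approx(0.5)

    def test_five_disease_toy_matches_pair_count(self, two_branch):
        rng = np.random.default_rng(3)
        terms = ["A1", "A2", "B1", "A", "B"]
        query = [
            PhenotypeProfile(f"DIS:{i}", frozenset(rng.choice(terms, size=2, replace=False)))
            for i in range(5)
        ]
        ref = [
            PhenotypeProfile(f"DIS:{i}", frozenset(rng.choice(terms, size=2, replace=False)))
            for i in range(5)
        ]
        matched = {f"DIS:{i}": f"DIS:{i}" for i in range(5)}
        ic = ic_from_profiles(query + ref, two_branch)
        res = reclassification_auc(query, ref, matched, ic=ic, g=two_branch, n_boot=10, seed=0)
        # brute force: count positive > negative comparisons, ties half
        sims = {}
        for a in query:
            for b in ref:
                sims[(a.disease, b.disease)] = profile_similarity(a, b, ic, two_branch)
        pos = [sims[(d, d)] for d in matched]
        neg = [v for (da, db), v in sims.items() if da != db]
        wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
        assert res.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self, two_branch):
        # AUC depends only on the similarity ranking, exercised by squashing IC
        rng = np.random.default_rng(4)
        terms = ["A1", "A2", "B1"]
        query = [PhenotypeProfile(f"DIS:{i}", frozenset({terms[i]})) for i in range(3)]
        matched = {p.disease: p.disease for p in query}
        ic1 = {k: v for k, v in IC.items()}
        res1 = reclassification_auc(query, query, matched, ic=ic1, g=two_branch, n_boot=10, seed=0)
        ic2 = {k: v**3 for k, v in IC.items()}  # strictly increasing on [0,1]
        res2 = reclassification_auc(query, query, matched, ic=ic2, g=two_branch, n_boot=10, seed=0)
        assert res1.auc == pytest.approx(res2.auc)

    def test_fewer_than_two_diseases_rejected(self, two_branch):
        p = PhenotypeProfile("DIS:0", frozenset({"A1"}))
        with pytest.raises(ValueError):
            reclassification_auc([p], [p], {"DIS:0": "DIS:0"}, g=two_branch)


class TestFacets:
    def test_inclusion_proportion(self, pain_chain):
        pairs = [("D", "HP:LOW"), ("D", "HP:BACK"), ("D", "HP:ABDO")] + [
            (f"D{i}", "HP:ABDO") for i in range(7)
        ]
        ic = {"HP:PAIN": 0.0, "HP:BACK": 0.9, "HP:LOW": 1.0, "HP:ABDO": 0.8}
        comps = facet_inclusion(pairs, ["HP:BACK"], pain_chain, ic, ic_min=0.6)
        assert comps[0].inclusion == pytest.approx(0.2)
        assert comps[0].count == 2

    def test_root_facet_dropped_by_ic_threshold(self, pain_chain):
        ic = {"HP:PAIN": 0.0, "HP:BACK": 0.9}
        comps = facet_inclusion([("D", "HP:LOW")], ["HP:PAIN"], pain_chain, ic, ic_min=0.6)
        assert comps == []

    def test_diamond_counted_once(self):
        g = OntologyGraph(
            [OntologyClass(x) for x in ["R", "F", "P1", "P2", "X"]],
            [("F", "R"), ("P1", "F"), ("P2", "F"), ("X", "P1"), ("X", "P2")],
        )
        ic = {"F": 0.9, "P1": 0.95, "P2": 0.95, "X": 1.0}
        comps = facet_inclusion([("D", "X")], ["F"], g, ic, ic_min=0.6)
        assert comps[0].count == 1

    def test_subsumption_correction_suppresses_shadowed_facet(self, pain_chain):
        # both facets cover exactly {(D, HP:LOW)}: report only the more specific
        ic = {"HP:PAIN": 0.7, "HP:BACK": 0.9, "HP:LOW": 1.0, "HP:ABDO": 0.8}
        comps = facet_inclusion(
            [("D", "HP:LOW")], ["HP:PAIN", "HP:BACK"], pain_chain, ic, ic_min=0.6
        )
        assert [c.facet for c in comps] == ["HP:BACK"]
        comps = facet_inclusion(
            [("D", "HP:LOW")], ["HP:PAIN", "HP:BACK"], pain_chain, ic, ic_min=0.6,
            suppress_subsumed=False,
        )
        assert {c.facet for c in comps} == {"HP:PAIN", "HP:BACK"}

    def test_expression_normalized_by_category_size(self, pain_chain):
        pairs = [("D", "HP:LOW"), ("E", "HP:BACK")]
        (comp,) = facet_expression(pairs, ["HP:BACK"], pain_chain)
        assert comp.inclusion == pytest.approx(2 / 2)  # 2 hits / {BACK, LOW}
        (raw,) = facet_expression(pairs, ["HP:BACK"], pain_chain, normalize="none")
        assert raw.inclusion == 2.0

    def test_category_proportions_non_exclusive(self):
        g = OntologyGraph(
            [OntologyClass(x) for x in ["R", "C1", "C2", "D1", "D2", "D3", "D4"]],
            [
                ("C1", "R"), ("C2", "R"),
                ("D1", "C1"), ("D2", "C1"), ("D3", "C2"),
                ("D4", "C1"), ("D4", "C2"),  # D4 in both categories
            ],
        )
        comps = {c.facet: c for c in category_proportions(["D1", "D2", "D3", "D4"], ["C1", "C2"], g)}
        assert comps["C1"].inclusion == pytest.approx(0.75)
        assert comps["C2"].inclusion == pytest.approx(0.5)
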