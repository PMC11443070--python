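"""Reference consolidation and subsumption-aware novelty / laconic subsets."""

import numpy as np
import pytest

from phemine.reference import (
    consolidate,
    laconic_subset,
    load_disease_link,
    novel_subset,
)

from conftest import make_random_dag


def _novel_oracle(pairs, ref_pairs, g):
    """Exhaustive double loop over the reference and the full ancestor sets."""
    out = {}
    for d, p in pairs:
        covered = False
        for rd, rp in ref_pairs:
            if rd == d and rp in g and p in g.ancestors(rp):
                covered = True
        out[(d, p)] = not covered
    return out


def _laconic_oracle(pairs, g):
    out = {}
    for d, p in pairs:
        strict_desc = g.descendants(p) - {p}
        out[(d, p)] = not any((d, c) in set(pairs) for c in strict_desc)
    return out


class TestConsolidate:
    def test_union_of_sources(self):
        ref = consolidate(
            {"A": [("d1", "p1")], "B": [("d1", "p1"), ("d1", "p2")]},
            link={"d1": "d1"},
        )
        assert ref.associations == {("d1", "p1"), ("d1", "p2")}

    def test_unlinked_diseases_flagged_and_excluded(self):
        ref = consolidate({"A": [("dX", "p1"), ("d1", "p2")]}, link={"d1": "DOID:1"})
        assert ref.unlinked == {"dX"}
        assert ref.associations == {("DOID:1", "p2")}

    def test_empty_sources_empty_set(self):
        ref = consolidate({})
        assert ref.associations == set()

    def test_tsv_sources_and_link_file(self, tmp_path):
        src = tmp_path / "a.tsv"
        src.write_text("disease_id\tphenotype_id\nICD:1\tHP:1\nICD:2\tHP:2\n")
        link_path = tmp_path / "link.tsv"
        link_path.write_text("ICD:1\tDOID:1\n")
        link = load_disease_link(link_path)
        ref = consolidate({"a": src}, link)
        assert ref.associations == {("DOID:1", "HP:1")}
        assert ref.unlinked == {"ICD:2"}

    def test_conflicting_link_rejected(self, tmp_path):
        path = tmp_path / "link.tsv"
        path.write_text("ICD:1\tDOID:1\nICD:1\tDOID:2\n")
        with pytest.raises(ValueError, match="conflicting"):
            load_disease_link(path)


class TestNovelty:
    def test_more_specific_reference_blocks_novelty(self, pain_chain):
        ref = consolidate({"r": [("D", "HP:LOW")]})
        (ann,) = novel_subset([("D", "HP:BACK")], ref, pain_chain)
        assert not ann.novel

    def test_incomparable_branch_is_novel(self, pain_chain):
        ref = consolidate({"r": [("D", "HP:LOW")]})
        (ann,) = novel_subset([("D", "HP:ABDO")], ref, pain_chain)
        assert ann.novel

    def test_exact_match_blocks_novelty(self, pain_chain):
        ref = consolidate({"r": [("D", "HP:BACK")]})
        (ann,) = novel_subset([("D", "HP:BACK")], ref, pain_chain)
        assert not ann.novel

    def test_more_general_reference_does_not_block(self, pain_chain):
        ref = consolidate({"r": [("D", "HP:PAIN")]})
        (ann,) = novel_subset([("D", "HP:BACK")], ref, pain_chain)
        assert ann.novel

    def test_empty_reference_all_novel_full_reference_none(self, pain_chain):
        pairs = [("D", "HP:LOW"), ("D", "HP:ABDO")]
        empty = consolidate({})
        assert all(a.novel for a in novel_subset(pairs, empty, pain_chain))
        full = consolidate({"r": pairs})
        assert not any(a.novel for a in novel_subset(pairs, full, pain_chain))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_subsumption_scan(self, seed):
        rng = np.random.default_rng(500 + seed)
        g, _ = make_random_dag(rng, 25, extra_edge_p=0.5)
        nodes = sorted(g.classes)
        diseases = ["D:1", "D:2"]
        pairs = [
            (diseases[int(rng.integers(2))], nodes[int(rng.integers(len(nodes)))])
            for _ in range(15)
        ]
        ref_pairs = [
            (diseases[int(rng.integers(2))], nodes[int(rng.integers(len(nodes)))])
            for _ in range(10)
        ]
        ref = consolidate({"r": ref_pairs})
        got = {a.pair: a.novel for a in novel_subset(pairs, ref, g)}
        want = _novel_oracle(pairs, ref_pairs, g)
        for pair in pairs:
            assert got[pair] == want[pair]

    @pytest.mark.parametrize("seed", range(5))
    def test_novelty_anti_monotone(self, seed):
        rng = np.random.default_rng(600 + seed)
        g, _ = make_random_dag(rng, 25, extra_edge_p=0.5)
        nodes = sorted(g.classes)
        ref_pairs = [("D", nodes[int(rng.integers(len(nodes)))]) for _ in range(6)]
        ref = consolidate({"r": ref_pairs})
        pairs = [("D", n) for n in nodes]
        novel = {a.pair[1]: a.novel for a in novel_subset(pairs, ref, g)}
        for n in nodes:
            if not novel[n]:
                for anc in g.ancestors(n):
                    assert not novel[anc]


class TestLaconic:
    def test_chain_keeps_most_specific(self, pain_chain):
        anns = laconic_subset([("D", "HP:PAIN"), ("D", "HP:BACK")], pain_chain)
        by_phe = {a.pair[1]: a.laconic for a in anns}
        assert by_phe == {"HP:PAIN": False, "HP:BACK": True}

    def test_single_association_is_laconic(self, pain_chain):
        (ann,) = laconic_subset([("D", "HP:PAIN")], pain_chain)
        assert ann.laconic

    def test_diamond_incomparable_children(self):
        from phemine.ontology import OntologyClass, OntologyGraph

        g = OntologyGraph(
            [OntologyClass(x) for x in ["P:0", "C:1", "C:2"]],
            [("C:1", "P:0"), ("C:2", "P:0")],
        )
        anns = laconic_subset([("D", "P:0"), ("D", "C:1"), ("D", "C:2")], g)
        by_phe = {a.pair[1]: a.laconic for a in anns}
        assert by_phe == {"P:0": False, "C:1": True, "C:2": True}

    def test_diseases_independent(self, pain_chain):
        anns = laconic_subset([("D1", "HP:PAIN"), ("D2", "HP:BACK")], pain_chain)
        assert all(a.laconic for a in anns)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_strict_descendant_scan(self, seed):
        rng = np.random.default_rng(700 + seed)
        g, _ = make_random_dag(rng, 25, extra_edge_p=0.5)
        nodes = sorted(g.classes)
        pairs = list(
            {
                ("D", nodes[int(rng.integers(len(nodes)))])
                for _ in range(12)
            }
        )
        got = {a.pair: a.laconic for a in laconic_subset(pairs, g)}
        want = _laconic_oracle(pairs, g)
        assert got == want

    @pytest.mark.parametrize("seed", range(5))
    def test_laconic_pairs_form_antichain(self, seed):
        rng = np.random.default_rng(800 + seed)
        g, _ = make_random_dag(rng, 30, extra_edge_p=0.5)
        nodes = sorted(g.classes)
        pairs = list({("D", nodes[int(rng.integers(len(nodes)))]) for _ in range(15)})
        laconic = [a.pair[1] for a in laconic_subset(pairs, g) if a.laconic]
        for a in laconic:
            for b in laconic:
                if a != b:
                    assert a not in g.ancestors(b) and b not in g.ancestors(a)
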