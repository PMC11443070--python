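"""Shared fixtures: tiny hand-built ontologies and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from phemine.ontology import OntologyClass, OntologyGraph
from phemine.transactions import TransactionRecord


@pytest.fixture
def pain_chain() -> OntologyGraph:
    """pain <- back pain <- low back pain, plus an unrelated abdominal branch."""
    classes = [
        OntologyClass("HP:PAIN", "pain"),
        OntologyClass("HP:BACK", "back pain"),
        OntologyClass("HP:LOW", "low back pain"),
        OntologyClass("HP:ABDO", "abdominal pain"),
    ]
    edges = [("HP:BACK", "HP:PAIN"), ("HP:LOW", "HP:BACK"), ("HP:ABDO", "HP:PAIN")]
    return OntologyGraph(classes, edges)


def make_random_dag(rng: np.random.Generator, n_nodes: int, extra_edge_p: float = 0.15):
    """Random rooted DAG: node i>0 gets one parent < i, plus extras.

    Returns (graph, edge list).  Construction guarantees acyclicity because
    edges always point from a higher index to a lower one.
    """
    classes = [OntologyClass(f"N:{i:03d}", f"node {i}") for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        edges.append((f"N:{i:03d}", f"N:{parent:03d}"))
        for cand in range(i):
            if cand != parent and rng.random() < extra_edge_p / i:
                edges.append((f"N:{i:03d}", f"N:{cand:03d}"))
    return OntologyGraph(classes, edges), edges


def oracle_ancestors(edges: list[tuple[str, str]], node: str) -> set[str]:
    """Exhaustive reflexive path search over the raw edge list."""
    acc = {node}
    frontier = [node]
    while frontier:
        x = frontier.pop()
        for child, parent in edges:
            if child == x and parent not in acc:
                acc.add(parent)
                frontier.append(parent)
    return acc


def oracle_propagated_counts(records, g):
    """Brute-force descendant-scan document counts, independent of the
    propagation machinery: a document counts for phenotype class Q iff any
    of its raw mentions is a descendant of Q (reflexive)."""
    all_phe = set()
    for r in records:
        for p in r.phenotype_ids:
            all_phe.update(g.ancestors(p))
    n_class: dict[str, int] = {}
    n_joint: dict[tuple[str, str], int] = {}
    diseases = sorted({d for r in records for d in r.disease_ids})
    for q in sorted(all_phe):
        desc = g.descendants(q)
        docs = [r for r in records if r.phenotype_ids & desc]
        n_class[q] = len(docs)
        for d in diseases:
            nj = sum(1 for r in docs if d in r.disease_ids)
            if nj:
                n_joint[(d, q)] = nj
    for d in diseases:
        n_class[d] = sum(1 for r in records if d in r.disease_ids)
    return n_class, n_joint


def random_corpus(rng: np.random.Generator, diseases, phenotypes, n_docs: int):
    """Small random corpus with skewed, independent mention probabilities."""
    records = []
    pd = 0.5 * rng.random(len(diseases))
    pp = 0.5 * rng.random(len(phenotypes))
    for i in range(n_docs):
        dis = frozenset(d for d, q in zip(diseases, pd) if rng.random() < q)
        phe = frozenset(p for p, q in zip(phenotypes, pp) if rng.random() < q)
        if not dis and not phe:
            continue
        records.append(
            TransactionRecord(doc_id=f"d{i}", source="rand", disease_ids=dis, phenotype_ids=phe)
        )
    return records
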