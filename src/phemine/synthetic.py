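"""Synthetic ontologies, corpora and reference sets with planted effects.

The generator emulates the statistical shape of an annotated social-media
corpus without any text: documents carry a small random number of disease
and phenotype class mentions; per-class marginal frequencies follow a
power law spanning orders of magnitude; a configurable set of planted
disease-phenotype dependencies raises the joint probability above the
independence background by a *lift* factor; and optional confounder pairs
co-occur (near-)perfectly, mimicking disease/phenotype classes that share a
label and are co-annotated by a keyword matcher.

Mentions are emitted at leaf classes only, so planted effects must surface
through superclass propagation — recovering a planted leaf effect at its
ancestors is the behaviour under test, not an artifact.

Document membership of class ``c`` is an independent Bernoulli draw with the
class's marginal frequency; the per-document mention count is therefore
Poisson-binomial with mean equal to the configured mentions-per-document
rate (the marginals are scaled to sum to it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .ontology import OntologyClass, OntologyGraph
from .reference import ReferenceAssociationSet, consolidate
from .transactions import TransactionRecord

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_ontology",
    "generate_corpus",
    "generate_reference",
    "auto_plant",
]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``mean_diseases_per_doc`` / ``mean_phenotypes_per_doc`` set the expected
    mention counts per document; ``marginal_exponent`` the power-law decay of
    per-class background frequencies (rank^-exponent); ``planted_pairs`` are
    (disease, phenotype, lift) triples where lift multiplies the phenotype's
    background probability inside documents mentioning the disease;
    ``confounder_pairs`` co-occur essentially perfectly at
    ``confounder_marginal`` frequency.
    """

    n_docs: int = 100_000
    n_diseases: int = 20
    n_phenotypes: int = 100
    mean_diseases_per_doc: float = 1.0
    mean_phenotypes_per_doc: float = 2.0
    marginal_exponent: float = 1.0
    max_marginal: float = 0.25
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    confounder_pairs: list[tuple[str, str]] = field(default_factory=list)
    confounder_marginal: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        for d, p, lift in self.planted_pairs:
            if lift < 1:
                raise ValueError(f"planted lift must be >= 1, got {lift} for ({d}, {p})")
        overlap = {(d, p) for d, p, _ in self.planted_pairs} & set(self.confounder_pairs)
        if overlap:
            raise ValueError(f"pairs cannot be both planted and confounder: {sorted(overlap)}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated corpus."""

    planted: set[tuple[str, str]]
    lifts: dict[tuple[str, str], float]
    confounders: set[tuple[str, str]]
    realized_marginals: dict[str, float]


def generate_ontology(
    depth: int,
    branching: int,
    seed: int = 0,
    extra_parent_prob: float = 0.0,
    prefix: str = "SC",
) -> OntologyGraph:
    """A rooted labelled class tree, optionally with extra multi-parent edges.

    Level ``k`` holds ``branching**k`` classes; with ``extra_parent_prob`` a
    class may gain one additional parent drawn from the level above (making
    the graph a DAG rather than a tree).  Deterministic per seed.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    classes: list[OntologyClass] = []
    edges: list[tuple[str, str]] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        cid = f"{prefix}:{counter:06d}"
        counter += 1
        return cid

    root = new_id()
    classes.append(OntologyClass(id=root, label=f"{prefix} root"))
    level = [root]
    for _ in range(depth):
        nxt = []
        for parent in level:
            for _ in range(branching):
                cid = new_id()
                classes.append(OntologyClass(id=cid, label=f"{prefix} term {cid.split(':')[1]}"))
                edges.append((cid, parent))
                if extra_parent_prob > 0 and len(level) > 1 and rng.random() < extra_parent_prob:
                    others = [x for x in level if x != parent]
                    edges.append((cid, others[int(rng.integers(len(others)))]))
                nxt.append(cid)
        level = nxt
    return OntologyGraph(classes, edges)


def _leaves(g: OntologyGraph) -> list[str]:
    return sorted(cid for cid in g.active_ids() if not g.children(cid))


def _background_marginals(
    classes: Sequence[str], mean_per_doc: float, exponent: float, max_marginal: float
) -> dict[str, float]:
    ranks = np.arange(1, len(classes) + 1, dtype=np.float64)
    w = ranks ** (-exponent)
    f = w * (mean_per_doc / w.sum())
    f = np.clip(f, 1e-12, max_marginal)
    return dict(zip(classes, f))


def auto_plant(
    g_dis: OntologyGraph,
    g_phe: OntologyGraph,
    cfg: GeneratorConfig,
    n_planted: int,
    lift: float,
    min_marginal: float = 0.005,
) -> list[tuple[str, str, float]]:
    """Deterministically choose planted pairs among adequately frequent leaves.

    Pairs up the first ``n_planted`` mentionable diseases with distinct
    phenotype leaves whose background marginal is at least ``min_marginal``.
    """
    dis = _leaves(g_dis)[: cfg.n_diseases]
    phe = _leaves(g_phe)[: cfg.n_phenotypes]
    f_phe = _background_marginals(
        phe, cfg.mean_phenotypes_per_doc, cfg.marginal_exponent, cfg.max_marginal
    )
    eligible = [p for p in phe if min_marginal <= f_phe[p] and lift * f_phe[p] <= 0.9]
    if len(eligible) < n_planted or len(dis) < 1:
        raise ValueError(
            f"cannot plant {n_planted} pairs: only {len(eligible)} phenotypes "
            f"reach marginal {min_marginal}"
        )
    return [(dis[i % len(dis)], eligible[i], lift) for i in range(n_planted)]


def generate_corpus(
    g_dis: OntologyGraph,
    g_phe: OntologyGraph,
    cfg: GeneratorConfig,
) -> tuple[list[TransactionRecord], SyntheticTruth]:
    """Sample an annotated corpus with planted effects; deterministic per seed.

    Mentionable classes are the first ``n_diseases`` / ``n_phenotypes`` leaf
    classes of each ontology.  Confounder pairs may name classes outside
    those lists; their columns are driven by a single shared indicator.
    """
    rng = np.random.default_rng(cfg.seed)
    dis_classes = _leaves(g_dis)[: cfg.n_diseases]
    phe_classes = _leaves(g_phe)[: cfg.n_phenotypes]
    if not dis_classes or not phe_classes:
        raise ValueError("ontologies provide no mentionable leaf classes")

    f_dis = _background_marginals(
        dis_classes, cfg.mean_diseases_per_doc, cfg.marginal_exponent, cfg.max_marginal
    )
    f_phe = _background_marginals(
        phe_classes, cfg.mean_phenotypes_per_doc, cfg.marginal_exponent, cfg.max_marginal
    )

    # confounders may extend the mentionable vocabulary
    for d, p in cfg.confounder_pairs:
        if d not in f_dis:
            if d not in g_dis:
                raise ValueError(f"confounder disease {d!r} not in ontology")
            dis_classes.append(d)
            f_dis[d] = cfg.confounder_marginal
        if p not in f_phe:
            if p not in g_phe:
                raise ValueError(f"confounder phenotype {p!r} not in ontology")
            phe_classes.append(p)
            f_phe[p] = cfg.confounder_marginal

    dis_idx = {c: i for i, c in enumerate(dis_classes)}
    phe_idx = {c: i for i, c in enumerate(phe_classes)}
    n = cfg.n_docs

    D = rng.random((n, len(dis_classes))) < np.array([f_dis[c] for c in dis_classes])
    P = rng.random((n, len(phe_classes))) < np.array([f_phe[c] for c in phe_classes])

    for d, p, lift in cfg.planted_pairs:
        if d not in dis_idx or p not in phe_idx:
            raise ValueError(f"planted pair ({d}, {p}) outside the mentionable vocabulary")
        q = lift * f_phe[p]
        if q > 1.0:
            import logging

            logging.getLogger(__name__).warning(
                "planted pair (%s, %s): lift %.3g clamps joint probability to 1", d, p, lift
            )
            q = 1.0
        with_d = D[:, dis_idx[d]]
        P[with_d, phe_idx[p]] = rng.random(int(with_d.sum())) < q

    for d, p in cfg.confounder_pairs:
        z = rng.random(n) < cfg.confounder_marginal
        D[:, dis_idx[d]] = z
        P[:, phe_idx[p]] = z

    width = max(6, len(str(n)))
    dis_rows, dis_cols = np.nonzero(D)
    phe_rows, phe_cols = np.nonzero(P)
    dis_sets: list[list[str]] = [[] for _ in range(n)]
    phe_sets: list[list[str]] = [[] for _ in range(n)]
    for r, c in zip(dis_rows.tolist(), dis_cols.tolist()):
        dis_sets[r].append(dis_classes[c])
    for r, c in zip(phe_rows.tolist(), phe_cols.tolist()):
        phe_sets[r].append(phe_classes[c])
    records = [
        TransactionRecord(
            doc_id=f"doc{i:0{width}d}",
            source="synthetic",
            disease_ids=frozenset(dis_sets[i]),
            phenotype_ids=frozenset(phe_sets[i]),
        )
        for i in range(n)
    ]

    realized = {c: float(D[:, i].mean()) for c, i in dis_idx.items()}
    realized.update({c: float(P[:, i].mean()) for c, i in phe_idx.items()})
    truth = SyntheticTruth(
        planted={(d, p) for d, p, _ in cfg.planted_pairs},
        lifts={(d, p): lift for d, p, lift in cfg.planted_pairs},
        confounders=set(cfg.confounder_pairs),
        realized_marginals=realized,
    )
    return records, truth


def generate_reference(
    truth: SyntheticTruth,
    g_phe: OntologyGraph,
    overlap: float = 1.0,
    specificity_shift: Literal["none", "generalize", "specialize"] = "none",
    seed: int = 0,
) -> ReferenceAssociationSet:
    """A reference set covering a controlled fraction of the planted truth.

    Each planted pair is included with probability ``overlap``; an included
    phenotype may be replaced by a random parent (``generalize``) or child
    (``specialize``) to exercise subsumption-aware novelty logic.  Classes
    with no parent/child are kept as-is.
    """
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs: set[tuple[str, str]] = set()
    for d, p in sorted(truth.planted):
        if rng.random() >= overlap:
            continue
        q = p
        if specificity_shift == "generalize":
            parents = sorted(g_phe.parents(p))
            if parents:
                q = parents[int(rng.integers(len(parents)))]
        elif specificity_shift == "specialize":
            children = sorted(g_phe.children(p))
            if children:
                q = children[int(rng.integers(len(children)))]
        elif specificity_shift != "none":
            raise ValueError(f"unknown specificity_shift {specificity_shift!r}")
        pairs.add((d, q))
    return consolidate({"synthetic_truth": pairs}, link=None)
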