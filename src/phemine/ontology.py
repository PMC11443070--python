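"""Subsumption hierarchies for phenotype and disease vocabularies.

An :class:`OntologyGraph` holds the asserted ``is_a`` structure of one
vocabulary (e.g. HPO for phenotypes, DO for diseases) as a directed acyclic
graph of subclass edges.  All reasoning in this package is reflexive-transitive
closure over those asserted edges: for the pure subclass hierarchies these
vocabularies ship, that closure coincides with what an OWL EL reasoner would
entail, without the dependency.

Information content (IC) follows Resnik: ``IC(x) = -log p(x)`` where ``p(x)``
is the propagated usage frequency of ``x`` relative to the root.  By default
IC is normalised to [0, 1] by the maximum finite IC observed, so thresholds
such as "drop facets below 0.6" are scale-free; raw (nat) IC is available via
``normalize=False``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyClass",
    "OntologyGraph",
    "OntologyError",
    "CycleError",
    "load_ontology",
    "resnik_ic",
]


class OntologyError(ValueError):
    """Malformed ontology input."""


class CycleError(OntologyError):
    """The subclass edge set contains a directed cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__(
            "subclass graph is cyclic, e.g. " + " -> ".join(cycle + cycle[:1])
        )


@dataclass(frozen=True)
class OntologyClass:
    """One ontology class (term)."""

    id: str
    label: str = ""
    synonyms: tuple[str, ...] = ()
    obsolete: bool = False


class OntologyGraph:
    """Directed acyclic subclass hierarchy with reflexive-transitive closure.

    Edges run child -> parent.  Obsolete classes are stored (and queryable by
    id) but take part in no edges, closures, or facet memberships.
    """

    def __init__(
        self,
        classes: Iterable[OntologyClass],
        subclass_edges: Iterable[tuple[str, str]],
    ):
        self.classes: dict[str, OntologyClass] = {}
        for cls in classes:
            if cls.id in self.classes:
                raise OntologyError(f"duplicate class id {cls.id!r}")
            self.classes[cls.id] = cls

        self._parents: dict[str, set[str]] = {cid: set() for cid in self.classes}
        self._children: dict[str, set[str]] = {cid: set() for cid in self.classes}
        dropped = 0
        for child, parent in subclass_edges:
            if child not in self.classes or parent not in self.classes:
                missing = child if child not in self.classes else parent
                raise OntologyError(f"edge references unknown class {missing!r}")
            if self.classes[child].obsolete or self.classes[parent].obsolete:
                dropped += 1
                continue
            self._parents[child].add(parent)
            self._children[parent].add(child)
        if dropped:
            logger.warning("dropped %d subclass edges touching obsolete classes", dropped)

        self._check_acyclic()
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}

    # -- construction helpers -------------------------------------------------

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._parents)
        for c, ps in self._parents.items():
            g.add_edges_from((c, p) for p in ps)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise CycleError([edge[0] for edge in cycle])

    # -- basic queries --------------------------------------------------------

    def __contains__(self, cid: str) -> bool:
        return cid in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def subclass_edges(self) -> set[tuple[str, str]]:
        return {(c, p) for c, ps in self._parents.items() for p in ps}

    @property
    def roots(self) -> list[str]:
        """Active classes with no parents."""
        return sorted(
            cid
            for cid, ps in self._parents.items()
            if not ps and not self.classes[cid].obsolete
        )

    def active_ids(self) -> list[str]:
        return sorted(cid for cid, c in self.classes.items() if not c.obsolete)

    def label(self, cid: str) -> str:
        return self.classes[cid].label

    def parents(self, cid: str) -> set[str]:
        self._require(cid)
        return set(self._parents[cid])

    def children(self, cid: str) -> set[str]:
        self._require(cid)
        return set(self._children[cid])

    def _require(self, cid: str) -> None:
        if cid not in self.classes:
            raise KeyError(f"unknown class id {cid!r}")

    # -- closures -------------------------------------------------------------

    def ancestors(self, cid: str) -> frozenset[str]:
        """Reflexive-transitive superclass set of ``cid`` (always contains it)."""
        self._require(cid)
        cached = self._anc_cache.get(cid)
        if cached is not None:
            return cached
        if self.classes[cid].obsolete:
            result = frozenset({cid})
        else:
            acc = {cid}
            stack = list(self._parents[cid])
            while stack:
                nxt = stack.pop()
                if nxt not in acc:
                    acc.add(nxt)
                    stack.extend(self._parents[nxt])
            result = frozenset(acc)
        self._anc_cache[cid] = result
        return result

    def descendants(self, cid: str) -> frozenset[str]:
        """Reflexive-transitive subclass set of ``cid``."""
        self._require(cid)
        cached = self._desc_cache.get(cid)
        if cached is not None:
            return cached
        if self.classes[cid].obsolete:
            result = frozenset({cid})
        else:
            acc = {cid}
            stack = list(self._children[cid])
            while stack:
                nxt = stack.pop()
                if nxt not in acc:
                    acc.add(nxt)
                    stack.extend(self._children[nxt])
            result = frozenset(acc)
        self._desc_cache[cid] = result
        return result

    def is_equal_or_more_specific(self, a: str, b: str) -> bool:
        """True iff ``a`` is subsumed by ``b`` (``b`` in ancestors(``a``))."""
        self._require(b)
        return b in self.ancestors(a)

    # -- facets ---------------------------------------------------------------

    def facet_members(self, facet_id: str) -> frozenset[str]:
        """Descendant closure of a designated top-level facet class.

        Membership is not exclusive: a class reachable from several facets
        belongs to all of them.
        """
        return self.descendants(facet_id)

    def facets(self, facet_ids: Iterable[str]) -> dict[str, frozenset[str]]:
        return {fid: self.facet_members(fid) for fid in facet_ids}

    # -- serialisation --------------------------------------------------------

    def to_edge_tsv(self, edge_path: str | Path, label_path: str | Path | None = None) -> None:
        with open(edge_path, "w") as fh:
            for child, parent in sorted(self.subclass_edges):
                fh.write(f"{child}\t{parent}\n")
        if label_path is not None:
            with open(label_path, "w") as fh:
                for cid in sorted(self.classes):
                    fh.write(f"{cid}\t{self.classes[cid].label}\n")


# -- loading ------------------------------------------------------------------


def _load_obo(path: str | Path) -> OntologyGraph:
    import obonet

    graph = obonet.read_obo(path, ignore_obsolete=False)
    classes = []
    edges = []
    for cid, data in graph.nodes(data=True):
        classes.append(
            OntologyClass(
                id=cid,
                label=data.get("name", ""),
                synonyms=tuple(data.get("synonym", ())),
                obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
            )
        )
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent))
    return OntologyGraph(classes, edges)


def _load_edge_tsv(path: str | Path, label_path: str | Path | None = None) -> OntologyGraph:
    edges: list[tuple[str, str]] = []
    ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise OntologyError(f"{path}:{lineno}: expected child<TAB>parent, got {line!r}")
            edges.append((parts[0], parts[1]))
            ids.update(parts)
    labels: dict[str, str] = {}
    if label_path is not None:
        with open(label_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise OntologyError(f"{label_path}:{lineno}: expected id<TAB>label")
                labels[parts[0]] = parts[1]
                ids.add(parts[0])
    classes = [OntologyClass(id=cid, label=labels.get(cid, cid)) for cid in sorted(ids)]
    return OntologyGraph(classes, edges)


def load_ontology(
    path: str | Path,
    format: str = "obo",
    label_path: str | Path | None = None,
) -> OntologyGraph:
    """Load an ontology from an OBO file or a two-column subclass edge TSV.

    Parameters
    ----------
    path:
        OBO file ([Term] stanzas; tags id/name/synonym/is_a/is_obsolete) or a
        TSV of ``child<TAB>parent`` subclass edges.
    format:
        ``"obo"`` or ``"edge_tsv"``.
    label_path:
        Optional ``id<TAB>label`` TSV accompanying an edge list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "obo":
        return _load_obo(path)
    if format == "edge_tsv":
        return _load_edge_tsv(path, label_path)
    raise ValueError(f"unknown ontology format {format!r}")


# -- information content -------------------------------------------------------


def resnik_ic(
    g: OntologyGraph,
    usage: Mapping[str, int],
    normalize: bool = True,
) -> dict[str, float]:
    """Resnik information content from propagated usage counts.

    ``usage`` must already obey the true-path rule (an ancestor's count is at
    least each descendant's count).  ``IC(x) = -log(usage(x) / usage_max)``
    where ``usage_max`` is the largest usage observed (the root under
    propagation).  Classes with zero or missing usage are omitted: their IC is
    undefined.  With ``normalize=True`` the values are divided by the maximum
    finite IC so the scale is [0, 1].
    """
    counts = {cid: int(n) for cid, n in usage.items() if int(n) > 0 and cid in g}
    if not counts:
        raise ValueError("empty usage map")
    for cid, n in counts.items():
        for parent in g.parents(cid):
            pn = counts.get(parent, 0)
            if pn < n:
                raise ValueError(
                    f"usage not monotone under subsumption: {parent} has {pn} < {cid} has {n}"
                )
    total = max(counts.values())
    ic = {cid: -math.log(n / total) for cid, n in counts.items()}
    if normalize:
        ic_max = max(ic.values())
        if ic_max > 0:
            ic = {cid: v / ic_max for cid, v in ic.items()}
    return ic
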