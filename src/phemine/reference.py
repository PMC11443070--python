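"""Reference association sets and subsumption-aware novelty annotation.

A reference set (the "background knowledge" analogue, e.g. associations
consolidated from biomedical databases and mined literature) is the union of
one or more source tables of disease -> phenotype pairs, after linking each
source's disease identifiers into the corpus disease vocabulary through an
explicit cross-reference map.  Source diseases with no link entry are kept
(flagged) but take no part in comparisons.

Against such a reference, a mined association (D, P) is

* **novel**  iff the reference holds no association (D, P') with P' equal to
  or more specific than P — the mined pair adds information the reference
  does not already carry, even implicitly;
* **laconic** iff among the *significant* mined associations of D there is
  none strictly more specific than P — the pair is maximally specific within
  its own significant set.  Laconic pairs form an antichain per disease.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .mining import AssociationScore
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceAssociationSet",
    "NoveltyAnnotation",
    "load_disease_link",
    "consolidate",
    "novel_subset",
    "laconic_subset",
    "write_novelty",
]


@dataclass
class ReferenceAssociationSet:
    """Union-consolidated disease -> phenotype reference associations."""

    sources: list[str]
    associations: set[tuple[str, str]]
    by_source: dict[str, set[tuple[str, str]]]
    disease_link: dict[str, str]
    unlinked: set[str]

    def phenotypes_of(self, disease: str) -> set[str]:
        return {p for d, p in self.associations if d == disease}


@dataclass(frozen=True)
class NoveltyAnnotation:
    pair: tuple[str, str]
    novel: bool
    laconic: bool = False


def load_disease_link(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping reference disease ids to corpus CURIEs."""
    link: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected source_id<TAB>corpus_id")
            src, dst = parts
            if src in link and link[src] != dst:
                raise ValueError(f"{path}:{lineno}: conflicting link for {src!r}")
            link[src] = dst
    return link


def _read_pairs(path: str | Path) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[:2] == ["disease_id", "phenotype_id"]:
                continue  # optional header
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected disease_id<TAB>phenotype_id")
            pairs.add((parts[0], parts[1]))
    return pairs


def consolidate(
    sources: Mapping[str, str | Path] | Mapping[str, Iterable[tuple[str, str]]],
    link: Mapping[str, str] | None = None,
) -> ReferenceAssociationSet:
    """Union reference sources into one maximal association set.

    ``sources`` maps source name to either a TSV path (columns disease_id,
    phenotype_id) or an iterable of pairs.  Disease ids are translated
    through ``link``; ids without a link entry are flagged ``unlinked`` and
    their associations excluded from the consolidated set.  An identity link
    is assumed when ``link`` is None.
    """
    if not sources:
        logger.warning("consolidating an empty source list: reference set is empty")
    by_source: dict[str, set[tuple[str, str]]] = {}
    for name, src in sources.items():
        if isinstance(src, (str, Path)):
            by_source[name] = _read_pairs(src)
        else:
            by_source[name] = {(d, p) for d, p in src}

    associations: set[tuple[str, str]] = set()
    unlinked: set[str] = set()
    for pairs in by_source.values():
        for d, p in pairs:
            if link is None:
                associations.add((d, p))
            elif d in link:
                associations.add((link[d], p))
            else:
                unlinked.add(d)
    if unlinked:
        logger.warning(
            "%d reference diseases have no cross-reference link and are "
            "excluded from comparison",
            len(unlinked),
        )
    return ReferenceAssociationSet(
        sources=sorted(by_source),
        associations=associations,
        by_source=by_source,
        disease_link=dict(link or {}),
        unlinked=unlinked,
    )


def novel_subset(
    mined: Sequence[AssociationScore | tuple[str, str]],
    ref: ReferenceAssociationSet,
    g: OntologyGraph,
) -> list[NoveltyAnnotation]:
    """Annotate each mined pair as novel or not against the reference.

    (D, P) is novel iff no reference phenotype of D is equal to or more
    specific than P.  Anti-monotone along subsumption: a non-novel pair
    forces all its phenotype ancestors' pairs non-novel too.
    """
    ref_by_disease: dict[str, set[str]] = defaultdict(set)
    for d, p in ref.associations:
        ref_by_disease[d].add(p)

    out: list[NoveltyAnnotation] = []
    for item in mined:
        d, p = (item.disease, item.phenotype) if isinstance(item, AssociationScore) else item
        if p not in g:
            raise KeyError(f"phenotype {p!r} absent from ontology")
        covered = any(
            prime in g and g.is_equal_or_more_specific(prime, p)
            for prime in ref_by_disease.get(d, ())
        )
        out.append(NoveltyAnnotation(pair=(d, p), novel=not covered))
    return out


def laconic_subset(
    significant: Sequence[AssociationScore | tuple[str, str]],
    g: OntologyGraph,
) -> list[NoveltyAnnotation]:
    """Annotate each significant pair as laconic (maximally specific) or not.

    (D, P) is laconic iff no other significant pair of D carries a phenotype
    strictly more specific than P.
    """
    pairs = [
        (item.disease, item.phenotype) if isinstance(item, AssociationScore) else item
        for item in significant
    ]
    by_disease: dict[str, set[str]] = defaultdict(set)
    for d, p in pairs:
        by_disease[d].add(p)
    out = []
    for d, p in pairs:
        has_more_specific = any(
            other != p and g.is_equal_or_more_specific(other, p)
            for other in by_disease[d]
        )
        out.append(NoveltyAnnotation(pair=(d, p), novel=False, laconic=not has_more_specific))
    return out


def write_novelty(
    scores: Sequence[AssociationScore],
    ref: ReferenceAssociationSet,
    g: OntologyGraph,
    path: str | Path,
) -> list[tuple[str, str, bool, bool, bool]]:
    """Emit a combined novelty table over the candidate associations.

    Novelty is computed over all candidate pairs; laconic only among the
    significant ones (False elsewhere).  Returns the rows written.
    """
    candidates = [s for s in scores if s.candidate]
    novel = {a.pair: a.novel for a in novel_subset(candidates, ref, g)}
    significant = [s for s in candidates if s.significant]
    laconic = {a.pair: a.laconic for a in laconic_subset(significant, g)}
    rows = []
    for s in candidates:
        pair = (s.disease, s.phenotype)
        rows.append(
            (s.disease, s.phenotype, novel[pair], laconic.get(pair, False), bool(s.significant))
        )
    with open(path, "w") as fh:
        fh.write("disease_id\tphenotype_id\tnovel\tlaconic\tsignificant\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return rows
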