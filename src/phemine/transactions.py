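"""Annotated document corpora ("transactions") and co-occurrence counting.

Each transaction is one document (e.g. one social-media post) carrying the
set of disease classes and the set of phenotype classes mentioned in it.
Phenotype mentions obey the true-path rule: before counting, every mention is
propagated to all its superclasses, so a mention of 'low back pain' also
counts as a mention of 'back pain' and 'pain'.  Disease mentions are NOT
propagated: the disease vocabulary in scope is a small curated list and
propagation would bias superclass counts through incomplete subclass coverage.

Counting is document-level and binary: a disease-phenotype pair co-occurs in
a document iff both appear at least once in it.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "TransactionRecord",
    "CooccurrenceCounts",
    "CorpusError",
    "load_corpus",
    "write_corpus",
    "propagate_phenotypes",
    "count_cooccurrence",
]

_TSV_HEADER = ["doc_id", "source", "disease_ids", "phenotype_ids"]


class CorpusError(ValueError):
    """Malformed corpus input."""


@dataclass(frozen=True)
class TransactionRecord:
    """One annotated document."""

    doc_id: str
    source: str = ""
    disease_ids: frozenset[str] = frozenset()
    phenotype_ids: frozenset[str] = frozenset()

    def is_empty(self) -> bool:
        return not self.disease_ids and not self.phenotype_ids


@dataclass
class CooccurrenceCounts:
    """Document-level counts feeding the NPMI score.

    ``n_class`` holds, per class, the number of documents mentioning it
    (post-propagation for phenotypes); ``n_joint`` the number of documents
    mentioning both members of a (disease, phenotype) pair.
    """

    n_tot: int
    n_class: dict[str, int]
    n_joint: dict[tuple[str, str], int]


def _parse_mentions(raw: str) -> frozenset[str]:
    if not raw:
        return frozenset()
    out = set()
    for tok in raw.split("|"):
        tok = tok.strip()
        if not tok:
            continue
        if ":" not in tok:
            raise CorpusError(f"malformed CURIE {tok!r}")
        out.add(tok)
    return frozenset(out)


def load_corpus(
    path: str | Path,
    format: Literal["tsv", "jsonl"] = "tsv",
    ontologies: Sequence[OntologyGraph] | None = None,
    unknown_curie: Literal["drop", "error"] = "drop",
    dedupe: bool = False,
) -> list[TransactionRecord]:
    """Load a transaction corpus from TSV or JSON-lines.

    TSV columns: ``doc_id, source, disease_ids, phenotype_ids`` with mention
    sets pipe-separated.  Records with both mention sets empty are dropped
    (count logged).  When ``ontologies`` is given, mentions of classes found
    in none of them are dropped with a warning or raise, per ``unknown_curie``.
    ``dedupe=True`` additionally collapses records with identical mention
    sets (identical-text deduplication is assumed to have happened upstream).
    """
    path = Path(path)
    records: list[TransactionRecord] = []
    seen_ids: set[str] = set()

    def push(doc_id: str, source: str, dis: frozenset[str], phe: frozenset[str]) -> None:
        if doc_id in seen_ids:
            raise CorpusError(f"duplicate doc_id {doc_id!r}")
        seen_ids.add(doc_id)
        records.append(TransactionRecord(doc_id, source, dis, phe))

    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _TSV_HEADER:
                raise CorpusError(f"expected header {_TSV_HEADER}, got {header}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise CorpusError(f"{path}:{lineno}: expected 4 columns")
                push(parts[0], parts[1], _parse_mentions(parts[2]), _parse_mentions(parts[3]))
    elif format == "jsonl":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                push(
                    str(obj["doc_id"]),
                    str(obj.get("source", "")),
                    frozenset(obj.get("disease_ids", ())),
                    frozenset(obj.get("phenotype_ids", ())),
                )
    else:
        raise ValueError(f"unknown corpus format {format!r}")

    if ontologies:
        known: set[str] = set()
        for g in ontologies:
            known.update(g.active_ids())
        cleaned: list[TransactionRecord] = []
        n_dropped_mentions = 0
        for rec in records:
            bad = (rec.disease_ids | rec.phenotype_ids) - known
            if bad:
                if unknown_curie == "error":
                    raise CorpusError(f"doc {rec.doc_id}: unknown class ids {sorted(bad)}")
                n_dropped_mentions += len(bad)
                rec = replace(
                    rec,
                    disease_ids=rec.disease_ids - bad,
                    phenotype_ids=rec.phenotype_ids - bad,
                )
            cleaned.append(rec)
        if n_dropped_mentions:
            logger.warning("dropped %d mentions of unknown classes", n_dropped_mentions)
        records = cleaned

    n_before = len(records)
    records = [r for r in records if not r.is_empty()]
    if len(records) < n_before:
        logger.info("dropped %d records with no mentions", n_before - len(records))

    if dedupe:
        seen_sets: set[tuple[frozenset[str], frozenset[str]]] = set()
        unique: list[TransactionRecord] = []
        for rec in records:
            key = (rec.disease_ids, rec.phenotype_ids)
            if key not in seen_sets:
                seen_sets.add(key)
                unique.append(rec)
        if len(unique) < len(records):
            logger.info("deduplicated %d identical records", len(records) - len(unique))
        records = unique

    return records


def write_corpus(records: Iterable[TransactionRecord], path: str | Path) -> None:
    """Write records as corpus TSV (round-trips through :func:`load_corpus`)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for rec in records:
            fh.write(
                f"{rec.doc_id}\t{rec.source}\t"
                f"{'|'.join(sorted(rec.disease_ids))}\t"
                f"{'|'.join(sorted(rec.phenotype_ids))}\n"
            )


def propagate_phenotypes(
    records: Sequence[TransactionRecord], g: OntologyGraph
) -> list[TransactionRecord]:
    """Expand each record's phenotype set to its full ancestor closure.

    Disease sets are left untouched.  Idempotent: ancestor closure is itself
    closed under ancestors.
    """
    out = []
    for rec in records:
        expanded: set[str] = set()
        for pid in rec.phenotype_ids:
            expanded.update(g.ancestors(pid))
        out.append(replace(rec, phenotype_ids=frozenset(expanded)))
    return out


def count_cooccurrence(
    records: Sequence[TransactionRecord],
    pairs: Literal["observed", "all"] = "observed",
) -> CooccurrenceCounts:
    """Exact document-level class and joint counts.

    ``pairs="observed"`` stores only (disease, phenotype) pairs co-occurring in
    at least one document; ``"all"`` additionally stores zero counts for every
    cross pair of observed classes.
    """
    if not records:
        raise CorpusError("empty corpus")
    n_class: Counter[str] = Counter()
    n_joint: Counter[tuple[str, str]] = Counter()
    diseases: set[str] = set()
    phenotypes: set[str] = set()
    for rec in records:
        for d in rec.disease_ids:
            n_class[d] += 1
        for p in rec.phenotype_ids:
            n_class[p] += 1
        diseases.update(rec.disease_ids)
        phenotypes.update(rec.phenotype_ids)
        for d in rec.disease_ids:
            for p in rec.phenotype_ids:
                n_joint[(d, p)] += 1
    joint: dict[tuple[str, str], int] = dict(n_joint)
    if pairs == "all":
        for d in diseases:
            for p in phenotypes:
                joint.setdefault((d, p), 0)
    return CooccurrenceCounts(n_tot=len(records), n_class=dict(n_class), n_joint=joint)
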