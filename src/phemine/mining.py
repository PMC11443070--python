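"""NPMI association scoring and the inclusion/exclusion filters.

The co-occurrence score is a normalised pointwise mutual information adapted
to ontology-propagated counts::

            log( n_joint * n_tot / (n_C * n_D) )
    npmi = --------------------------------------
                 -log( n_joint / n_tot )

with natural logarithms (the value is invariant to the log base, since the
base cancels in the ratio).  npmi lies in [-1, 1]: 0 at exact independence,
1 at perfect co-occurrence (joint count equal to both marginals), approaching
-1 as the joint probability vanishes relative to the marginals.  Unobserved
pairs (zero joint count) are never scored.

Filters, applied in order (the first matching tag wins):

1. ``low_frequency`` — either class appears in fewer than
   ``min_class_fraction`` of documents (default 0.01%), guarding against
   unstable scores for very rare classes;
2. ``nonpositive``  — npmi <= 0; only positive associations are of interest;
3. ``collinear``    — npmi >= ``collinearity_cutoff`` (default 0.75), which
   removes near-perfect co-occurrences such as disease/phenotype classes that
   share a label and are co-annotated by the upstream keyword matcher;
4. ``blocklist``    — the phenotype is on a configured blocklist (the manual
   label-review exclusions).

Untagged pairs form the candidate association set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .transactions import CooccurrenceCounts

__all__ = ["AssociationScore", "MiningConfig", "npmi", "score_all", "write_associations", "read_associations"]


def npmi(n_joint: int, n_C: int, n_D: int, n_tot: int) -> float:
    """Normalised pointwise mutual information of one observed pair.

    Requires ``1 <= n_joint <= min(n_C, n_D)`` and ``n_C, n_D <= n_tot``.
    The degenerate case ``n_joint == n_tot`` (the pair in every document)
    returns 1 by continuity.
    """
    if n_tot < 1:
        raise ValueError("n_tot must be >= 1")
    if n_joint < 1:
        raise ValueError("npmi undefined for zero joint count")
    if n_joint > min(n_C, n_D) or max(n_C, n_D) > n_tot:
        raise ValueError(
            f"inconsistent counts: n_joint={n_joint}, n_C={n_C}, n_D={n_D}, n_tot={n_tot}"
        )
    if n_joint == n_tot or n_joint == n_C == n_D:
        return 1.0
    pmi = math.log(n_joint * n_tot / (n_C * n_D))
    h = -math.log(n_joint / n_tot)
    return min(1.0, max(-1.0, pmi / h))


@dataclass
class MiningConfig:
    """Filter settings for association mining."""

    min_class_fraction: float = 0.0001
    collinearity_cutoff: float = 0.75
    collinear_strict: bool = False
    blocklist: frozenset[str] = frozenset()
    keep_nonpositive: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_class_fraction < 1):
            raise ValueError("min_class_fraction must be in (0, 1)")
        if not (0 < self.collinearity_cutoff <= 1):
            raise ValueError("collinearity_cutoff must be in (0, 1]")
        self.blocklist = frozenset(self.blocklist)


@dataclass
class AssociationScore:
    """One scored disease-phenotype pair."""

    disease: str
    phenotype: str
    n_joint: int
    n_disease: int
    n_phenotype: int
    npmi: float
    p_value: Optional[float] = None
    q_value: Optional[float] = None
    significant: Optional[bool] = None
    excluded_by: Optional[str] = None

    @property
    def candidate(self) -> bool:
        return self.excluded_by is None


def score_all(counts: CooccurrenceCounts, cfg: MiningConfig | None = None) -> list[AssociationScore]:
    """Score every observed pair and tag exclusions.

    Returns one :class:`AssociationScore` per observed pair in a deterministic
    (sorted) order.  ``excluded_by`` carries the first filter that fired;
    untagged scores are the candidate set.
    """
    cfg = cfg or MiningConfig()
    min_docs = cfg.min_class_fraction * counts.n_tot

    # strict collinearity mode bans both classes of any offending pair
    banned: set[str] = set()
    if cfg.collinear_strict:
        for (d, p), nj in counts.n_joint.items():
            if nj == 0:
                continue
            nd = counts.n_class[d]
            np_ = counts.n_class[p]
            if nd >= min_docs and np_ >= min_docs:
                if npmi(nj, np_, nd, counts.n_tot) >= cfg.collinearity_cutoff:
                    banned.update((d, p))

    out: list[AssociationScore] = []
    for (d, p) in sorted(counts.n_joint):
        nj = counts.n_joint[(d, p)]
        if nj == 0:
            continue
        nd = counts.n_class[d]
        np_ = counts.n_class[p]
        score = npmi(nj, np_, nd, counts.n_tot)
        tag: Optional[str] = None
        if nd < min_docs or np_ < min_docs:
            tag = "low_frequency"
        elif score <= 0 and not cfg.keep_nonpositive:
            tag = "nonpositive"
        elif score >= cfg.collinearity_cutoff or d in banned or p in banned:
            tag = "collinear"
        elif p in cfg.blocklist:
            tag = "blocklist"
        out.append(
            AssociationScore(
                disease=d,
                phenotype=p,
                n_joint=nj,
                n_disease=nd,
                n_phenotype=np_,
                npmi=score,
                excluded_by=tag,
            )
        )
    return out


_COLUMNS = [
    "disease_id",
    "phenotype_id",
    "n_joint",
    "n_disease",
    "n_phenotype",
    "npmi",
    "excluded_by",
    "p_value",
    "q_value",
    "significant",
]


def to_dataframe(scores: Iterable[AssociationScore]) -> pd.DataFrame:
    rows = [
        (
            s.disease,
            s.phenotype,
            s.n_joint,
            s.n_disease,
            s.n_phenotype,
            s.npmi,
            s.excluded_by or "",
            s.p_value,
            s.q_value,
            s.significant,
        )
        for s in scores
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_associations(scores: Iterable[AssociationScore], path: str | Path) -> None:
    to_dataframe(scores).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_associations(path: str | Path) -> list[AssociationScore]:
    df = pd.read_csv(path, sep="\t", dtype={"excluded_by": str}, keep_default_na=False, na_values=[""])
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AssociationScore(
                disease=row.disease_id,
                phenotype=row.phenotype_id,
                n_joint=int(row.n_joint),
                n_disease=int(row.n_disease),
                n_phenotype=int(row.n_phenotype),
                npmi=float(row.npmi),
                excluded_by=(row.excluded_by or None) if isinstance(row.excluded_by, str) else None,
                p_value=None if pd.isna(row.p_value) else float(row.p_value),
                q_value=None if pd.isna(row.q_value) else float(row.q_value),
                significant=None if pd.isna(row.significant) else bool(row.significant),
            )
        )
    return out
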