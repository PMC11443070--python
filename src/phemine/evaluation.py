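"""Model-to-model evaluation: semantic similarity AUC and facet composition.

Two phenotype models (sets of disease profiles) are compared by Resnik
semantic similarity: the similarity of two phenotype classes is the
information content of their most informative common ancestor, and profiles
are aggregated by best-match average (BMA).  The *reclassification AUC* then
asks: given a disease's profile in one model, how well does similarity
ranking recover that same disease's profile in the other model?  It is the
Mann-Whitney probability that a matched (same-disease) profile pair scores
above a non-matched pair, ties counting one half; the confidence interval
comes from a bootstrap over diseases.

Thematic composition is described by *facets*: designated high-level ontology
classes whose descendant closures define categories (membership is not
exclusive).  Inclusion is the fraction of associations whose phenotype falls
under a facet; expression optionally normalises the count by the facet's own
ontology size, so large categories do not dominate by mere breadth.
Uninformative facets (normalised IC below a threshold, default 0.6) are
dropped, and a facet is suppressed when a reported strict sub-facet covers
exactly the same associations (subsumption correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .ontology import OntologyGraph, resnik_ic

__all__ = [
    "PhenotypeProfile",
    "AUCResult",
    "FacetComposition",
    "ic_from_profiles",
    "term_similarity",
    "profile_similarity",
    "reclassification_auc",
    "facet_inclusion",
    "facet_expression",
    "category_proportions",
]


@dataclass(frozen=True)
class PhenotypeProfile:
    """The set of phenotypes one model associates with one disease."""

    disease: str
    phenotypes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phenotypes", frozenset(self.phenotypes))


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_diseases: int


@dataclass(frozen=True)
class FacetComposition:
    facet: str
    inclusion: float
    count: int


def ic_from_profiles(
    profiles: Iterable[PhenotypeProfile],
    g: OntologyGraph,
    normalize: bool = True,
) -> dict[str, float]:
    """Resnik IC from annotation usage pooled over the given profiles.

    Each (disease, phenotype) annotation contributes one usage count to the
    phenotype and every ancestor (true-path propagation).  Pool both models'
    profiles when comparing them, so similarities share one IC scale.
    """
    usage: dict[str, int] = {}
    for prof in profiles:
        for p in prof.phenotypes:
            for anc in g.ancestors(p):
                usage[anc] = usage.get(anc, 0) + 1
    return resnik_ic(g, usage, normalize=normalize)


def term_similarity(p: str, q: str, ic: Mapping[str, float], g: OntologyGraph) -> float:
    """Resnik similarity: max IC over the common ancestors of two classes."""
    common = g.ancestors(p) & g.ancestors(q)
    return max((ic[a] for a in common if a in ic), default=0.0)


def profile_similarity(
    a: PhenotypeProfile,
    b: PhenotypeProfile,
    ic: Mapping[str, float],
    g: OntologyGraph,
    aggregation: Literal["bma", "avg_pairwise"] = "bma",
) -> float:
    """Groupwise Resnik similarity of two phenotype profiles.

    ``bma`` (best-match average, the default) averages each side's best
    match and takes the mean of the two directions; ``avg_pairwise`` is the
    mean over the full pairwise matrix.  Symmetric in both modes.
    """
    if not a.phenotypes or not b.phenotypes:
        raise ValueError("profile similarity undefined for empty profiles")
    pa = sorted(a.phenotypes)
    pb = sorted(b.phenotypes)
    mat = np.array([[term_similarity(p, q, ic, g) for q in pb] for p in pa])
    if aggregation == "bma":
        return float((mat.max(axis=1).mean() + mat.max(axis=0).mean()) / 2.0)
    if aggregation == "avg_pairwise":
        return float(mat.mean())
    raise ValueError(f"unknown aggregation {aggregation!r}")


def _auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counting one half."""
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def reclassification_auc(
    query: Sequence[PhenotypeProfile],
    ref: Sequence[PhenotypeProfile],
    matched: Mapping[str, str],
    ic: Optional[Mapping[str, float]] = None,
    g: OntologyGraph | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    aggregation: Literal["bma", "avg_pairwise"] = "bma",
) -> AUCResult:
    """AUC for recovering matched diseases across two phenotype models.

    Each query profile (one model) is scored against every reference profile
    (other model).  Positives are matched-disease similarities, negatives all
    cross-disease ones; the CI is a seeded percentile bootstrap over diseases.
    IC defaults to propagated usage pooled over both models' profiles.
    """
    if g is None:
        raise ValueError("an ontology is required")
    query = [p for p in query if p.disease in matched]
    ref_by_id = {p.disease: p for p in ref}
    query = [p for p in query if matched[p.disease] in ref_by_id]
    n = len(query)
    if n < 2:
        raise ValueError("need at least 2 matched diseases")
    if ic is None:
        ic = ic_from_profiles(list(query) + list(ref), g)

    ref_cols = [ref_by_id[matched[p.disease]] for p in query]
    sim = np.array(
        [[profile_similarity(a, b, ic, g, aggregation) for b in ref_cols] for a in query]
    )
    eye = np.eye(n, dtype=bool)
    auc = _auc(sim[eye], sim[~eye])

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    same_disease = np.array(
        [[ref_cols[j].disease == matched[query[i].disease] for j in range(n)] for i in range(n)]
    )
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = sim[np.ix_(idx, idx)]
        # resampled duplicates make some off-diagonal cells matched pairs;
        # keep the positive/negative split faithful to disease identity
        sub_match = same_disease[np.ix_(idx, idx)]
        pos = sub[np.diag_indices(n)]
        neg = sub[~sub_match]
        try:
            boots[b] = _auc(pos, neg)
        except ValueError:
            boots[b] = np.nan
    valid = boots[~np.isnan(boots)]
    lo, hi = np.percentile(valid, [2.5, 97.5]) if valid.size else (auc, auc)
    return AUCResult(auc=auc, ci_low=float(lo), ci_high=float(hi), n_diseases=n)


# ---------------------------------------------------------------------------
# facet composition
# ---------------------------------------------------------------------------


def _facet_members(
    pairs: Sequence[tuple[str, str]], facet: str, g: OntologyGraph
) -> set[tuple[str, str]]:
    scope = g.facet_members(facet)
    return {pair for pair in pairs if pair[1] in scope}


def facet_inclusion(
    pairs: Sequence[tuple[str, str]],
    facets: Sequence[str],
    g: OntologyGraph,
    ic: Mapping[str, float],
    ic_min: float = 0.6,
    suppress_subsumed: bool = True,
) -> list[FacetComposition]:
    """Fraction of associations whose phenotype falls under each facet.

    Facets whose normalised IC is undefined or below ``ic_min`` are dropped
    (they are too general to be informative).  With ``suppress_subsumed``,
    a facet is also dropped when a strict descendant facet in the same list
    covers an identical association set — reporting both would duplicate
    one theme at two levels of generality.
    """
    distinct = list(dict.fromkeys(pairs))
    total = len(distinct)
    kept: list[tuple[str, set[tuple[str, str]]]] = []
    for f in facets:
        if f not in g:
            raise KeyError(f"unknown facet {f!r}")
        if ic.get(f, -1.0) < ic_min:
            continue
        kept.append((f, _facet_members(distinct, f, g)))
    out = []
    for f, members in kept:
        if suppress_subsumed:
            shadowed = any(
                f2 != f and g.is_equal_or_more_specific(f2, f) and members2 == members
                for f2, members2 in kept
            )
            if shadowed:
                continue
        out.append(
            FacetComposition(
                facet=f,
                inclusion=len(members) / total if total else 0.0,
                count=len(members),
            )
        )
    return out


def facet_expression(
    pairs: Sequence[tuple[str, str]],
    facets: Sequence[str],
    g: OntologyGraph,
    normalize: Literal["none", "by_category_size"] = "by_category_size",
) -> list[FacetComposition]:
    """Facet counts, optionally normalised by the facet's ontology size.

    ``by_category_size`` divides the association count under a facet by the
    number of ontology classes in the facet's descendant closure, so a theme
    is not over-represented merely because its category defines more classes.
    """
    distinct = list(dict.fromkeys(pairs))
    out = []
    for f in facets:
        members = _facet_members(distinct, f, g)
        if normalize == "by_category_size":
            size = len(g.facet_members(f))
            if size == 0:
                raise ValueError(f"facet {f!r} has no descendants")
            value = len(members) / size
        elif normalize == "none":
            value = float(len(members))
        else:
            raise ValueError(f"unknown normalization {normalize!r}")
        out.append(FacetComposition(facet=f, inclusion=value, count=len(members)))
    return out


def category_proportions(
    diseases: Sequence[str],
    disease_facets: Sequence[str],
    g: OntologyGraph,
) -> list[FacetComposition]:
    """Per disease-category proportion of diseases falling under each facet.

    Membership is non-exclusive: a disease under two categories contributes
    to both, so proportions need not sum to 1.
    """
    distinct = list(dict.fromkeys(diseases))
    total = len(distinct)
    out = []
    for f in disease_facets:
        scope = g.facet_members(f)
        count = sum(1 for d in distinct if d in scope)
        out.append(
            FacetComposition(
                facet=f,
                inclusion=count / total if total else 0.0,
                count=count,
            )
        )
    return out
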