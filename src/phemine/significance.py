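"""Monte Carlo significance for NPMI scores, with q-value FDR control.

The null model asks: how large an NPMI score would this disease-phenotype
pair reach if mentions were assigned to documents at random, holding fixed
everything except the association itself?  A randomised corpus has the *same
size and shape* as the original: the same number of documents, the same
number of disease slots and phenotype slots per document, and exactly the
same per-class marginal mention counts.  This is achieved by independently
permuting, across documents, the flattened occurrence list of disease
mentions and that of raw phenotype mentions; permutations that land two
copies of one class in the same document are repaired by swapping one copy
with a randomly chosen slot elsewhere (bounded retries).  Phenotype slots
carry *raw* mentions: superclass propagation is re-run inside every
replicate, so the null correctly reflects propagation-induced dependence.

Pairs absent from a replicate (zero joint count) contribute the NPMI infimum
-1, keeping every null at exactly ``n_replicates`` samples and giving the
empirical p-value a fixed resolution of ``1/(n_replicates+1)``.

P-values are one-sided (upper tail): either empirical,
``p = (1 + #{null >= observed}) / (1 + B)``, never zero; or ``normal_fit``,
the upper-tail probability of a normal distribution fitted to the null mean
and standard deviation (the replicate score distributions are close to
normal for well-populated pairs; a skewness diagnostic is emitted).

False discovery rate control uses Storey q-values with the smoother
(cubic-fit) estimate of the null proportion pi0; with pi0 fixed at 1 the
procedure coincides with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .mining import AssociationScore
from .ontology import OntologyGraph
from .transactions import TransactionRecord

__all__ = [
    "NullModelConfig",
    "NullDistribution",
    "randomize_corpus",
    "null_distributions",
    "p_value",
    "q_values",
    "estimate_pi0",
    "flag_significant",
    "assign_significance",
]

NPMI_INF = -1.0  # infimum score assigned to pairs absent from a replicate


@dataclass
class NullModelConfig:
    """Settings for the Monte Carlo null."""

    n_replicates: int = 2000
    seed: int = 0
    scheme: Literal["shuffle_class_lists"] = "shuffle_class_lists"
    p_method: Literal["empirical", "normal_fit"] = "empirical"
    fdr: float = 0.0005
    keep_samples: bool = True

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if self.scheme != "shuffle_class_lists":
            raise ValueError(f"unknown randomization scheme {self.scheme!r}")


@dataclass
class NullDistribution:
    """Summary of one pair's replicate NPMI scores."""

    pair: tuple[str, str]
    count: int
    mean: float
    sd: float
    samples: Optional[np.ndarray] = None
    normality_stat: float = float("nan")  # sample skewness of the replicate scores


# ---------------------------------------------------------------------------
# encoded corpus: flattened slot arrays, one per vocabulary
# ---------------------------------------------------------------------------


class _EncodedCorpus:
    """Flattened slot representation of a corpus for fast shuffling.

    For each vocabulary the corpus becomes two parallel arrays: the class
    index occupying each mention slot, and the document index owning it.
    Permuting the class array while leaving the document array fixed
    preserves n_tot, every per-document slot count, and every per-class
    marginal count.
    """

    def __init__(self, records: Sequence[TransactionRecord]):
        if not records:
            raise ValueError("empty corpus")
        self.doc_ids = [r.doc_id for r in records]
        self.sources = [r.source for r in records]
        self.n_docs = len(records)

        dis_vocab: set[str] = set()
        phe_vocab: set[str] = set()
        for r in records:
            dis_vocab.update(r.disease_ids)
            phe_vocab.update(r.phenotype_ids)
        self.dis_ids = sorted(dis_vocab)
        self.phe_ids = sorted(phe_vocab)
        dis_index = {c: i for i, c in enumerate(self.dis_ids)}
        phe_index = {c: i for i, c in enumerate(self.phe_ids)}

        def flatten(index: dict[str, int], attr: str) -> tuple[np.ndarray, np.ndarray]:
            flat, doc = [], []
            for di, r in enumerate(records):
                for c in sorted(getattr(r, attr)):
                    flat.append(index[c])
                    doc.append(di)
            return (
                np.asarray(flat, dtype=np.int64),
                np.asarray(doc, dtype=np.int64),
            )

        self.dis_flat, self.dis_doc = flatten(dis_index, "disease_ids")
        self.phe_flat, self.phe_doc = flatten(phe_index, "phenotype_ids")

    def to_records(
        self, dis_flat: np.ndarray, phe_flat: np.ndarray
    ) -> list[TransactionRecord]:
        dis_sets: list[set[str]] = [set() for _ in range(self.n_docs)]
        phe_sets: list[set[str]] = [set() for _ in range(self.n_docs)]
        for ci, di in zip(dis_flat.tolist(), self.dis_doc.tolist()):
            dis_sets[di].add(self.dis_ids[ci])
        for ci, di in zip(phe_flat.tolist(), self.phe_doc.tolist()):
            phe_sets[di].add(self.phe_ids[ci])
        return [
            TransactionRecord(
                doc_id=self.doc_ids[i],
                source=self.sources[i],
                disease_ids=frozenset(dis_sets[i]),
                phenotype_ids=frozenset(phe_sets[i]),
            )
            for i in range(self.n_docs)
        ]


def _in_sorted(sorted_arr: np.ndarray, values: np.ndarray) -> np.ndarray:
    pos = np.searchsorted(sorted_arr, values)
    pos = np.minimum(pos, sorted_arr.size - 1)
    return sorted_arr[pos] == values


def _shuffle_slots(
    flat: np.ndarray,
    doc: np.ndarray,
    n_classes: int,
    rng: np.random.Generator,
    max_rounds: int = 80,
) -> np.ndarray:
    """Permute slot contents and repair within-document duplicates by swaps.

    Each repair round proposes, for every remaining duplicate slot, a swap
    with one uniformly random slot; a proposal is accepted when it creates
    no new within-document duplicate and does not conflict with another
    accepted proposal.  Rounds repeat until clean (bounded)."""
    if flat.size == 0:
        return flat.copy()
    for _restart in range(12):
        out = _try_shuffle(flat, doc, n_classes, rng, max_rounds)
        if out is not None:
            return out
    raise RuntimeError(
        "slot shuffle could not repair within-document duplicates "
        "(degenerate corpus: too few distinct classes for the slot counts)"
    )


def _try_shuffle(
    flat: np.ndarray,
    doc: np.ndarray,
    n_classes: int,
    rng: np.random.Generator,
    max_rounds: int,
) -> np.ndarray | None:
    out = flat[rng.permutation(flat.size)]
    n = out.size

    keys = doc * n_classes + out
    order = np.argsort(keys, kind="stable")
    sk = keys[order]
    dup = np.empty(n, dtype=bool)
    dup[0] = False
    np.equal(sk[1:], sk[:-1], out=dup[1:])
    remaining = order[dup]
    # membership of keys created by accepted swaps (absent from the stale sk);
    # keys vacated by swaps stay "present" in sk, which only rejects
    # conservatively and never admits a duplicate
    added = np.empty(0, dtype=keys.dtype)

    rounds = 0
    while remaining.size:
        if rounds >= max_rounds:
            return None  # re-permute and retry from scratch
        rounds += 1
        j = rng.integers(0, n, size=remaining.size)
        ci = out[remaining]
        cj = out[j]
        key_i_new = doc[remaining] * n_classes + cj
        key_j_new = doc[j] * n_classes + ci
        ok = (j != remaining) & (ci != cj)
        ok &= ~_in_sorted(sk, key_i_new) & ~_in_sorted(sk, key_j_new)
        if added.size:
            ok &= ~_in_sorted(added, key_i_new) & ~_in_sorted(added, key_j_new)
        # reject proposals sharing a slot or producing a repeated new key
        slots_used = np.concatenate([remaining[ok], j[ok]])
        uniq_slots, slot_counts = np.unique(slots_used, return_counts=True)
        if (slot_counts > 1).any():
            multi = uniq_slots[slot_counts > 1]
            ok &= ~np.isin(remaining, multi) & ~np.isin(j, multi)
        new_keys = np.concatenate([key_i_new[ok], key_j_new[ok]])
        uniq_keys, key_counts = np.unique(new_keys, return_counts=True)
        if (key_counts > 1).any():
            bad = uniq_keys[key_counts > 1]
            ok &= ~np.isin(key_i_new, bad) & ~np.isin(key_j_new, bad)
        sel = remaining[ok]
        jj = j[ok]
        out[sel], out[jj] = out[jj], out[sel].copy()
        added = np.sort(np.concatenate([added, key_i_new[ok], key_j_new[ok]]))
        remaining = remaining[~ok]
    return out


def randomize_corpus(
    records: Sequence[TransactionRecord], seed: int
) -> list[TransactionRecord]:
    """One marginal-preserving randomisation of the corpus.

    Preserves the number of documents, each document's disease- and
    phenotype-slot counts, and every per-class marginal mention count;
    destroys disease-phenotype co-assignment.  Deterministic per seed.
    """
    enc = _EncodedCorpus(records)
    rng = np.random.default_rng(seed)
    dis = _shuffle_slots(enc.dis_flat, enc.dis_doc, len(enc.dis_ids), rng)
    phe = _shuffle_slots(enc.phe_flat, enc.phe_doc, len(enc.phe_ids), rng)
    return enc.to_records(dis, phe)


# ---------------------------------------------------------------------------
# per-replicate counting (propagation re-run inside each replicate)
# ---------------------------------------------------------------------------


class _NullEngine:
    def __init__(
        self,
        records: Sequence[TransactionRecord],
        g: OntologyGraph,
        pairs: Sequence[tuple[str, str]],
    ):
        self.enc = _EncodedCorpus(records)
        enc = self.enc

        # ancestor-closure indicator over the raw phenotype vocabulary
        closure: set[str] = set()
        anc_sets = []
        for pid in enc.phe_ids:
            anc = g.ancestors(pid)
            anc_sets.append(anc)
            closure.update(anc)
        self.phe_all = sorted(closure)
        all_index = {c: i for i, c in enumerate(self.phe_all)}
        rows, cols = [], []
        for raw_i, anc in enumerate(anc_sets):
            for a in anc:
                rows.append(raw_i)
                cols.append(all_index[a])
        self.A = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int32), (rows, cols)),
            shape=(len(enc.phe_ids), len(self.phe_all)),
        )

        dis_index = {c: i for i, c in enumerate(enc.dis_ids)}
        self.pairs = list(pairs)
        self.pair_d = np.asarray([dis_index[d] for d, _ in pairs], dtype=np.int64)
        self.pair_p = np.asarray([all_index[p] for _, p in pairs], dtype=np.int64)

        # disease marginals are invariant under the shuffle
        self.n_dis = np.bincount(enc.dis_flat, minlength=len(enc.dis_ids)).astype(np.int64)
        self.n_tot = enc.n_docs
        self._dis_ones = np.ones(enc.dis_flat.size, dtype=np.int32)
        self._phe_ones = np.ones(enc.phe_flat.size, dtype=np.int32)

    def replicate_scores(self, rng: np.random.Generator) -> np.ndarray:
        enc = self.enc
        dis = _shuffle_slots(enc.dis_flat, enc.dis_doc, len(enc.dis_ids), rng)
        phe = _shuffle_slots(enc.phe_flat, enc.phe_doc, len(enc.phe_ids), rng)
        return self.scores_for(dis, phe)

    def scores_for(self, dis_flat: np.ndarray, phe_flat: np.ndarray) -> np.ndarray:
        enc = self.enc
        R = sp.csr_matrix(
            (self._phe_ones, (enc.phe_doc, phe_flat)),
            shape=(self.n_tot, len(enc.phe_ids)),
        )
        P = R @ self.A
        P.data.fill(1)  # binarize: document-level mention, not multiplicity
        n_phe = np.asarray(P.sum(axis=0)).ravel().astype(np.int64)
        D = sp.csr_matrix(
            (self._dis_ones, (enc.dis_doc, dis_flat)),
            shape=(self.n_tot, len(enc.dis_ids)),
        )
        joint = (D.T @ P).toarray().astype(np.int64)
        nj = joint[self.pair_d, self.pair_p]
        return _npmi_vec(nj, n_phe[self.pair_p], self.n_dis[self.pair_d], self.n_tot)


def _npmi_vec(nj: np.ndarray, n_c: np.ndarray, n_d: np.ndarray, n_tot: int) -> np.ndarray:
    """Vectorised NPMI; zero joint counts map to the infimum -1."""
    out = np.full(nj.shape, NPMI_INF, dtype=np.float64)
    pos = nj > 0
    if pos.any():
        njp = nj[pos].astype(np.float64)
        pmi = np.log(njp * n_tot) - np.log(n_c[pos].astype(np.float64) * n_d[pos])
        h = np.log(n_tot) - np.log(njp)
        full = (njp == n_tot) | ((nj[pos] == n_c[pos]) & (nj[pos] == n_d[pos]))
        val = np.empty(njp.shape)
        nz = ~full
        val[nz] = pmi[nz] / h[nz]
        val[full] = 1.0
        out[pos] = np.clip(val, -1.0, 1.0)
    return out


def null_distributions(
    records: Sequence[TransactionRecord],
    g: OntologyGraph,
    cfg: NullModelConfig,
    pairs: Sequence[tuple[str, str]],
) -> dict[tuple[str, str], NullDistribution]:
    """Replicate NPMI null distributions for the given candidate pairs.

    ``records`` must carry *raw* (un-propagated) phenotype mentions;
    propagation is applied inside each replicate.  Every pair receives
    exactly ``cfg.n_replicates`` samples; replicates where the pair has zero
    joint count contribute the infimum score -1.
    """
    engine = _NullEngine(records, g, pairs)
    rng = np.random.default_rng(cfg.seed)
    samples = np.empty((len(pairs), cfg.n_replicates), dtype=np.float64)
    for b in range(cfg.n_replicates):
        samples[:, b] = engine.replicate_scores(rng)
    out: dict[tuple[str, str], NullDistribution] = {}
    for i, pair in enumerate(pairs):
        row = samples[i]
        sd = float(row.std(ddof=1)) if cfg.n_replicates > 1 else 0.0
        out[pair] = NullDistribution(
            pair=pair,
            count=cfg.n_replicates,
            mean=float(row.mean()),
            sd=sd,
            samples=row.copy() if cfg.keep_samples else None,
            normality_stat=float(stats.skew(row))
            if cfg.n_replicates > 2 and sd > 0
            else float("nan"),
        )
    return out


# ---------------------------------------------------------------------------
# p-values and q-values
# ---------------------------------------------------------------------------


def p_value(
    observed: float,
    null: NullDistribution,
    method: Literal["empirical", "normal_fit"] = "empirical",
) -> float:
    """One-sided upper-tail p-value of an observed score against its null."""
    if method == "normal_fit":
        if null.count < 8:
            raise ValueError("normal_fit requires >= 8 null samples")
        if null.sd > 0:
            # floor guards against underflow to exactly 0 for extreme scores
            return float(max(stats.norm.sf(observed, loc=null.mean, scale=null.sd), 1e-300))
        method = "empirical"  # degenerate null: fall back
    if method == "empirical":
        if null.samples is None:
            raise ValueError("empirical p-value requires stored null samples")
        b = null.samples.size
        return float((1 + int(np.sum(null.samples >= observed))) / (1 + b))
    raise ValueError(f"unknown p-value method {method!r}")


def estimate_pi0(p: np.ndarray) -> float:
    """Storey's smoother estimate of the proportion of true nulls.

    Evaluates pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a grid and
    extrapolates with a cubic fit to the right end of the grid, clamped to
    [1/m, 1].
    """
    m = p.size
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0s = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0s, 3)
    pi0 = float(np.polyval(coef, lambdas[-1]))
    return float(min(1.0, max(pi0, 1.0 / m)))


def q_values(p: Sequence[float], pi0: Optional[float] = None) -> np.ndarray:
    """Storey q-values for a collection of p-values.

    With ``pi0=1`` this is exactly Benjamini-Hochberg adjustment.  ``pi0``
    is estimated with the smoother when not given and at least 100 p-values
    are available; below that the estimate is unstable and pi0 falls back
    to 1 (conservative).  Output order matches input order.
    """
    parr = np.asarray(p, dtype=np.float64)
    if parr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if parr.size == 0:
        return parr.copy()
    if np.any((parr <= 0) | (parr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = parr.size
    if pi0 is None:
        pi0 = estimate_pi0(parr) if m >= 100 else 1.0
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(parr, kind="stable")
    ranked = parr[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m, dtype=np.float64)
    out[order] = q
    return out


def flag_significant(
    scores: Sequence[AssociationScore], fdr: float = 0.0005
) -> list[AssociationScore]:
    """Set ``significant = (q_value <= fdr)`` on every score carrying a q-value."""
    for s in scores:
        if s.q_value is not None:
            s.significant = s.q_value <= fdr
    return list(scores)


def assign_significance(
    scores: Sequence[AssociationScore],
    records: Sequence[TransactionRecord],
    g: OntologyGraph,
    cfg: NullModelConfig,
) -> list[AssociationScore]:
    """Run the full null -> p -> q -> flag chain on the candidate scores.

    ``records`` is the raw (un-propagated) corpus; only candidate (untagged)
    scores receive p/q/significance, matching the mining contract that
    excluded pairs are withdrawn from testing.
    """
    candidates = [s for s in scores if s.candidate]
    if not candidates:
        return list(scores)
    pairs = [(s.disease, s.phenotype) for s in candidates]
    nulls = null_distributions(records, g, cfg, pairs)
    for s in candidates:
        s.p_value = p_value(s.npmi, nulls[(s.disease, s.phenotype)], cfg.p_method)
    qs = q_values([s.p_value for s in candidates])
    for s, q in zip(candidates, qs):
        s.q_value = float(q)
    flag_significant(candidates, cfg.fdr)
    return list(scores)
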