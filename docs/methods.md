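# Methods

This note documents the statistical model behind `phemine`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do and
do not establish about behaviour on real corpora.

## Transactions and propagation

The unit of observation is one document carrying a *set* of disease classes
and a *set* of phenotype classes (duplicate mentions within a document
collapse). Phenotype mentions are expanded to their full reflexive-transitive
superclass closure before counting, so a specific mention also evidences
every more general phenotype. Disease mentions are deliberately not
propagated: the disease vocabulary in a targeted corpus is a curated list,
and superclass counts composed from incomplete subclass coverage would be
biased. All subsumption reasoning is closure over asserted is-a edges; for
pure subclass hierarchies (the HPO/DO case) this coincides with what an EL
reasoner entails, without the dependency.

Co-occurrence is document-level and binary: a pair co-occurs in a document
iff both classes appear at least once. No windowing, author modelling, or
temporal structure is used.

## The NPMI score and filters

Each observed pair is scored with normalised pointwise mutual information
(natural logs; the ratio is invariant to the base),
`npmi = log(n_joint·n_tot/(n_C·n_D)) / (−log(n_joint/n_tot))`. Unobserved
pairs (zero joint count) are never scored — the method targets positive
associations, for which the score's −1 limit is irrelevant. Filters run in a
fixed, observable order:

1. **low_frequency** — either class in fewer than `min_class_fraction`
   (default 10⁻⁴, i.e. 0.01 %) of documents. Applied to post-propagation
   phenotype counts and raw disease counts — the same counts that enter the
   score — with the raw-count alternative available by scoring un-propagated
   records.
2. **nonpositive** — npmi ≤ 0.
3. **collinear** — npmi ≥ `collinearity_cutoff` (default 0.75). This targets
   disease/phenotype class pairs that share a label and are therefore
   co-annotated by keyword matchers on nearly every occurrence. The default
   removes the offending *pair* only, since the stated purpose is shared-label
   pairs; `collinear_strict=True` removes both classes wholesale, for
   corpora where a mechanically co-annotated class should not be trusted in
   any pair.
4. **blocklist** — a configured set of phenotypes excluded after manual
   label review.

A pair matching several filters carries the first tag only, which makes the
filter cascade auditable from the output table.

One documented *non*-property: replacing a phenotype by an ancestor never
decreases the joint count, but it does not in general increase (or preserve)
npmi, because the ancestor's marginal grows too. No code may rely on
monotonicity of npmi along subsumption.

## Monte Carlo null and p-values

The null model must destroy disease–phenotype co-assignment while holding
fixed every term of the score that is not the association itself. A
randomised corpus therefore preserves: the document count, each document's
disease-slot and phenotype-slot counts, and every per-class marginal mention
count. This is achieved by independently permuting the flattened occurrence
lists of disease mentions and of raw phenotype mentions across documents.
Permutations that land two copies of a class in one document are repaired by
swapping one copy with a uniformly chosen slot elsewhere, accepting only
swaps that create no new duplicate; repair rounds repeat until clean, with a
full re-permutation restart if a configuration stalls (only near-degenerate
corpora — slot counts close to the vocabulary size — ever restart). Phenotype
slots carry raw mentions and propagation is re-run inside every replicate,
so the null inherits propagation-induced dependence between a class and its
ancestors.

Pairs absent from a replicate contribute the score infimum −1. Every null
therefore has exactly B samples and the empirical p-value
`p = (1 + #{null ≥ observed})/(1 + B)` has fixed resolution 1/(B+1), is
never 0 and never exceeds 1. The default B is 2000.

Two p-value readings are provided. `empirical` is the default and is
assumption-free. `normal_fit` evaluates the upper tail of a normal fitted to
the null mean and standard deviation; replicate score distributions are
close to normal for well-populated pairs (a skewness diagnostic is emitted
per pair), and the parametric tail is the only way to resolve p-values below
1/(B+1). This matters when the FDR threshold is far below the empirical
resolution: at B = 500 and ~10³ tested pairs, no empirical p-value can ever
produce q ≤ 5·10⁻⁴, so planted-effect benchmarks and any analysis at that
FDR with moderate B should use `normal_fit`. Testing is one-sided (upper
tail) throughout, consistent with the restriction to positive associations.

## q-values

False discovery rate control uses Storey q-values. The null proportion π₀
is estimated with the smoother: π₀(λ) = #{p > λ}/(m(1−λ)) on the grid
λ = 0.05, …, 0.95, extrapolated by a cubic polynomial fit evaluated at the
right end of the grid and clamped to [1/m, 1]. With fewer than 100 p-values
the estimate is unstable and π₀ falls back to 1, which reduces the procedure
to Benjamini–Hochberg (also available explicitly via `pi0=1`). q-values are
monotone in p-rank, capped at 1, order-invariant, and the boundary rule is
inclusive: q equal to the FDR threshold (default 0.0005) counts as
significant.

## Reference comparison

Reference sources are consolidated by union after translating their disease
identifiers through an explicit cross-reference map; diseases with no link
entry are flagged and excluded from comparison rather than silently dropped.
No automatic identifier resolution or synonym-level matching is attempted —
equivalence is class identity plus subsumption only.

`novel(D, P)` holds iff the reference contains no (D, P′) with P′ ⊑ P. This
is anti-monotone along subsumption (a non-novel pair forces all ancestor
pairs non-novel), and is computed over all candidate associations with the
significant subset reported separately. `laconic(D, P)` holds, among the
significant pairs of D, iff none is strictly more specific than P; the
laconic pairs of a disease form an antichain — the maximally specific
frontier of its significant profile.

## Similarity, AUC, facets

Term similarity is Resnik: the maximum information content over common
ancestors, with IC(x) = −log(usage(x)/usage(root)) from propagated
annotation usage. IC is normalised by the maximum finite IC to [0, 1] by
default, making thresholds transferable across corpora; raw nat-valued IC is
available (`normalize=False`). When two models are compared, IC is computed
from their pooled profiles so both sides score on one scale.

Profile similarity aggregates the pairwise matrix by best-match average
(mean of each side's best match, averaged over the two directions), the de
facto standard for phenotype profiles; full-matrix mean is available. The
reclassification AUC ranks each query profile's similarity to every
reference profile: positives are matched-disease pairs, negatives all cross
pairs, and the AUC is the Mann–Whitney probability with ties counting ½ —
invariant under any strictly increasing transform of similarities. The
confidence interval is a seeded percentile bootstrap over diseases (2000
resamples by default); resampled duplicates are kept in the positive set and
excluded from negatives by disease identity.

Facet composition treats designated high-level classes as themes.
*Inclusion* is the fraction of associations whose phenotype falls in the
facet's descendant closure (each association counted once per facet,
regardless of multiple paths; membership across facets is non-exclusive).
Facets with normalised IC below `ic_min` (default 0.6) are dropped as
uninformative, and a facet whose member set is identical to that of a
reported strict descendant facet is suppressed — reporting both would state
one theme at two generality levels. This suppression rule is one reading of
subsumption correction and sits behind a flag (`suppress_subsumed`).
*Expression* divides the facet count by the facet's own ontology size so a
theme is not over-represented merely because its branch defines more
classes. Disease-category proportions are analogous over diseases.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical shape of an annotated social-media
corpus: documents with small random mention counts, per-class marginal
frequencies following a power law (rank⁻¹ by default, capped at 0.25)
spanning orders of magnitude, planted disease–phenotype dependencies, and
shared-label confounders. Document membership of each class is an
independent Bernoulli draw at the class's marginal; marginals are scaled to
sum to the configured mean mentions per document (1 disease, 2 phenotypes by
default), so per-document counts are Poisson-binomial with that mean. A
planted pair (D, P, lift) multiplies P's probability by `lift` inside
documents mentioning D; a confounder pair ties both classes to one shared
indicator, producing npmi = 1 — exactly the signature the collinearity
filter exists to remove. Mentions are emitted at leaf classes only, so
planted effects must surface through propagation; benchmark defaults are
100,000 documents, 20 diseases, 100 phenotypes, lift 5 on marginals ≥ 0.5 %,
with B = 500 replicates (B reduced from the 2000 production default to keep
the benchmark's Monte Carlo cost proportionate; the empirical-p resolution
argument above then mandates `normal_fit` for the FDR-0.0005 recovery runs).

What passing these benchmarks does *not* show: robustness to annotation
error and sense ambiguity (mentions here are exact), to correlated documents
(duplicates, reposts, prolific authors), to non-stationary topic drift, or
to dependence structures among phenotypes beyond ontology subsumption. Real
corpora have all of these; the benchmarks establish the statistical
machinery, not the NER layer above it.

## Numerical and degenerate-input conventions

- npmi is clamped to [−1, 1]; perfect co-occurrence and full-corpus joint
  counts return exactly 1 by continuity.
- normal-fit p-values are floored at 10⁻³⁰⁰ to avoid exact zeros after
  underflow; a zero-sd null falls back to the empirical p.
- Ties in AUC count ½ via midranks.
- Obsolete ontology classes load but are excluded from closures, facets and
  scoring; edges touching them are dropped with a warning. Cycles reject the
  ontology outright.
- Empty documents are dropped on load (counted in the log); an entirely
  empty corpus is a stage error.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; a full pipeline run is byte-identical given
  (config, seed).

## Known limitations

- The randomisation repair can fail (with a diagnostic) on corpora where
  slot counts approach the vocabulary size; such corpora are outside the
  method's intended regime.
- π₀ estimation needs a few hundred p-values to be worth using; small
  analyses silently run at the conservative BH limit.
- The facet suppression rule requires *identical* member sets; nearly
  identical facets are both reported.
- The AUC compares query profiles against reference profiles in one
  direction (each model's profile queried against the other's set) rather
  than pooling both directions.
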