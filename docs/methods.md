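# Methods

## Model

A catalog is an ordered collection of miRNA categories; each category is
a named set of miRNAs sharing one curated property, labelled with one of
five classes: `family`, `cluster`, `function`, `disease`, `tissue`. The
background population for testing is the catalog universe (the union of
all category members), or a user-supplied background list intersected
with that universe.

Given population size `P`, input hits `HP`, category size `S` and
category/input overlap `HS`, the overlap under the null of random
membership is hypergeometric:

    Pr(X = HS) = C(HP, HS) · C(P − HP, S − HS) / C(P, S)

Over-representation is scored by the upper tail `Σ_{h=HS}^{S} Pr(X = h)`
and depletion by the lower tail `Σ_{h=0}^{HS} Pr(X = h)`. The upper sum
formally runs to `S`; terms with `h > HP` are over-drawn binomial
coefficients and contribute zero, so the literal summation bound is kept.
The two tails share the `HS` term, so `p_over + p_under − pmf = 1`
exactly, which the suite verifies on random count tuples.

With a custom background, category sizes are recomputed inside the
background before testing, so that all four counts refer to a single urn;
categories that fall below `min_category_size` (default 2) after
truncation are skipped and logged, since a degenerate urn can only return
p = 1.

Raw p-values are adjusted by Bonferroni (`min(1, p·m)`) and
Benjamini–Hochberg step-up FDR. By default one correction family spans
all categories tested in a run; `--per-class` restricts the family to
each category class. Both behaviours are exposed because the choice is a
modelling judgement, not a mathematical one.

## Prediction of novel related miRNAs

Because categories group miRNAs directly rather than via predicted
targets, an enriched category's members that are absent from the input
are natural candidates for involvement in the same process. The
prediction step emits, for every category with raw p ≤ α (or FDR q ≤ α
with `use_fdr`), one record per unmatched member. Raw-p gating at
α = 0.05 is the default because per-category evidence is what nominates a
candidate; a conservative family-wise gate would suppress exactly the
moderate signals (p ≈ 0.01–0.05) this screen is meant to surface. A
miRNA backed by several significant categories appears once per category;
the summary view deduplicates, ranking by best supporting p, then by the
number of supporting categories, then by name.

Only over-representation results may nominate: a depleted category argues
against its remaining members, so passing an under-representation table
to the prediction step is a usage error.

## Catalog construction

* **Clusters.** Single-linkage chaining of miRNA gene loci per
  chromosome: two genes are linked when the gap between their intervals
  (left end to right start, 0 for overlap) is ≤ 50,000 bp, inclusive —
  the empirical distance within which clustered miRNAs are co-expressed.
  The gap is measured between interval boundaries rather than start to
  start so the rule is insensitive to precursor lengths; the exact
  boundary is inclusive, and both choices are pinned by oracle tests.
  Strand is ignored by default (`--same-strand` restricts chaining), as
  clustered miRNAs on opposite strands can still share a locus. Clusters
  are named for their natural-sort first member ("mir-199a cluster").
* **Families.** One category per sequence family (miRBase-style table or
  miFam stanza file) with ≥ 2 distinct members after normalization;
  singletons are dropped with a log line — a one-member set cannot be
  enriched and only inflates the correction burden. The same singleton
  rule applies to clusters by construction.
* **Tissue sets.** miRNAs with tissue specificity index ≥ 0.7
  (inclusive; TSI ∈ [0, 1], 1 = single-tissue) grouped by tissue label.
  TSI values are consumed, never computed from expression data.
* **Function/disease sets.** Curated membership tables, one category per
  set name, rows unioned, provenance recorded in the display name.

Identifiers are normalized throughout: lowercase, whitespace removed, and
a 3–4 letter species prefix (`hsa-`, `rno-`, `mmu-` …) stripped when the
remainder begins with `mir` or `let` — so `let-7a` is never mangled, and
rat microarray names match human categories by stem. Arm suffixes
(`-5p`/`-3p`) are preserved: merging arms silently would conflate
distinct mature species.

## Numerical choices

* Exact integer/rational arithmetic for tails whenever `P ≤ 10⁴` — the
  realistic regime, since curated catalogs span a few hundred distinct
  miRNAs — giving bit-stable p-values; log-gamma summation above that,
  cross-checked against an independent library implementation.
* Results are sorted by raw p, ties broken by category id, so output
  tables are byte-identical across runs.
* Corrections are delegated to a standard statistics library and held to
  naive O(m²) reference implementations in the tests.

## Synthetic data and the packaged example

The fixture generators emulate the *shape* of real resources — catalogs
with all five classes over a reserved `mir-s#` namespace, gene loci whose
inter-gene gaps straddle the 50 kb boundary, TSI tables spanning the 0.7
threshold — as pure functions of a seeded spec. They do not emulate real
miRNA name idiosyncrasies, expression noise, or the correlation structure
of real categories (real families and clusters overlap heavily), so
passing tests demonstrate algorithmic correctness, not biological
calibration of any threshold.

The packaged worked example is the AMI microarray signature: 8 up- and 8
downregulated miRNAs, with the 11-member muscle-development function
category. Of those 11 members, 2 (miR-1, miR-499) are inputs. The
category database behind the original analysis is not redistributed, and
its background size is unpublished, so the published per-category
enrichment p-values are not recomputable from this package's fixtures; at
a nominal population of 400 the upper tail for this overlap evaluates to
0.067 rather than the published 0.04, consistent with an unpublished,
somewhat larger background or with inputs dropped during matching. The
worked example therefore gates the category at its published significance
(0.04) and recomputes everything downstream — matching, counts, and the
nine nominated candidates. `scripts/acceptance.py` performs exactly this
run (category size 11, input list 16) and finishes in well under a second.

## Limitations

* Category curation is out of scope: the package reads and writes the
  GMT-dialect catalog format but ships no curated catalog beyond the
  worked example.
* Cross-species matching is by normalized name stem only; no ortholog
  mapping is attempted.
* The hypergeometric null assumes exchangeable miRNAs; correlated
  categories (families nested in clusters) make the Bonferroni column
  conservative.
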