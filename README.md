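# mirenrich

Enrichment and depletion analysis of curated **miRNA category sets** for a
list of miRNAs — e.g. the deregulated miRNAs from a microarray or
small-RNA-seq experiment — plus prediction of novel related miRNAs.

Tools that annotate miRNA lists through *predicted targets* inherit the
high false-positive/false-negative rates of target prediction. The
alternative implemented here groups miRNAs **directly** into curated
categories — sequence families, genomic clusters (genes within 50 kb),
functions, associated diseases, and tissue-specific sets (tissue
specificity index ≥ 0.7) — and asks, for each category, whether the input
list overlaps it more (or less) than chance.

## The statistic

With a background population of `P` miRNAs (the catalog universe, or a
user-supplied background), `HP` of which are inputs, a category of size
`S` containing `HS` inputs follows the hypergeometric model

```
Pr(X = HS) = C(HP, HS) · C(P − HP, S − HS) / C(P, S)
```

Over-representation is the upper tail `Σ_{h=HS..S} Pr(X = h)` and
under-representation the lower tail `Σ_{h=0..HS} Pr(X = h)`; tails are
computed exactly (rational arithmetic) for `P ≤ 10⁴`. Raw p-values across
all tested categories are adjusted by Bonferroni and Benjamini–Hochberg
FDR. Members of significantly enriched categories that are *absent* from
the input list are nominated as candidate novel related miRNAs.

## Worked example

The packaged example is an acute myocardial infarction (AMI) microarray
signature: 8 upregulated plus 8 downregulated miRNAs, analysed against a
small catalog containing the 11-member *muscle development* function
category.

```python
from mirenrich import run_enrichment
from mirenrich.fixtures import ami_fixture, ami_catalog

ex = ami_fixture()
results = run_enrichment(list(ex.deregulated), ami_catalog())
muscle = next(r for r in results if r.category_id == "muscle-development")
print(muscle.HS, muscle.S, sorted(muscle.matched_members))
```

prints

```
2 11 ['mir-1', 'mir-499']
```

two of the category's 11 members (miR-1 and miR-499) are among the 16
input miRNAs. Gating the category as significant (it was reported at
p = 0.04 against its full catalog, which is not redistributed here),
prediction nominates the other nine members:

```python
import dataclasses
from mirenrich import predict_related
from mirenrich.catalog import normalize_names
from mirenrich.fixtures import MUSCLE_DEVELOPMENT_REPORTED_P as p

marked = dataclasses.replace(muscle, p_raw=p, p_bonferroni=p, p_fdr=p)
hits = frozenset(normalize_names(ex.deregulated))
print(sorted(r.mirna for r in predict_related([marked], hits, alpha=0.05)))
```

```
['mir-124', 'mir-133a', 'mir-133b', 'mir-206', 'mir-208b',
 'mir-221', 'mir-222', 'mir-23a', 'mir-24']
```

nine candidate novel AMI-related miRNAs.

## Command line

```sh
# build catalogs from raw resources
mirenrich build cluster --gff mirnas.gff3 --max-gap 50000 --out clusters.gmt
mirenrich build family  --table families.tsv --out families.gmt
mirenrich build tissue  --tsi tsi.tsv --threshold 0.7 --out tissue.gmt
mirenrich build merge   clusters.gmt families.gmt tissue.gmt --out catalog.gmt

# score an input list, then nominate novel candidates
mirenrich enrich input.txt catalog.gmt --direction over --out results.tsv
mirenrich predict results.tsv input.txt --alpha 0.05 --out predictions.tsv
```

Catalogs are GMT-dialect set files (`<id> TAB class=<label> TAB members…`);
results and predictions are TSV; every run writes a JSON manifest
recording options and any dropped identifiers. Exit codes: 0 success,
1 usage error, 2 data/format error.

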