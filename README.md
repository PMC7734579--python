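# genepriority

Multi-evidence functional annotation and prioritization of disease
candidate genes, with every annotation category benchmarked against a
random-gene-set null.

Candidate gene lists produced by genetic studies of complex disorders
(the package's motivating use case is autism spectrum disorder, where
hundreds of genes are implicated) are too long for direct clinical
follow-up. This package prioritizes the genes most likely to be
clinically relevant by requiring convergent evidence across four
independent annotation categories:

1. **Brain expression** — expressed at ≥ 0.5 TPM in at least one brain
   region of a tissue-expression matrix;
2. **Mouse knockout trait** — carries a confidently mapped one-to-one
   mouse ortholog (≥ 2 prediction tools, best score in both mapping
   directions) whose knockout shows an association (*p* ≤ 0.05, either
   sex) to a phenotype term under a top-level Mammalian Phenotype branch
   linked — via distance-1 ontology cross-mapping — to biological
   processes overrepresented among the candidates in *both* species;
3. **Drug relevance** — an approved-drug target (Tclin), a chemically
   tractable target (Tchem), or a literature-significant pharmacogenomic
   variant;
4. **Actionable-panel interaction** — a direct protein–protein
   interaction (confidence ≥ 0.4) with a product of a clinically
   actionable (ACMG secondary-findings) gene.

## Statistical model

For each category the observed candidate count *x* of *n* genes is
compared against the mean proportion *p₀* over *K* = 1000 random sets of
*n* protein-coding genes with a continuity-corrected one-proportion
chi-square test,

```
χ² = n · ( max(0, |x/n − p₀| − 1/(2n)) )² / ( p₀ (1 − p₀) ),   df = 1
```

with a 95% Wilson score interval (continuity-corrected) and
Benjamini–Hochberg adjustment across the eight reported categories; the
all-categories intersection is tested separately and reported
unadjusted. Process overrepresentation uses the **parent–child**
variant of the one-sided hypergeometric test — each term is conditioned
on the union of its parents' annotated gene sets, removing the
inheritance bias of term-by-term tests on a DAG — with Bonferroni
selection at α = 0.05/*n* over the *n* tested nodes. Expression profiles
are compared with a two-group MANOVA (Pillai's trace with its exact-F
conversion) on region-wise log₂(TPM+1) vectors plus BH-adjusted
per-region F tests, and actionable-interaction counts with a
Kruskal–Wallis rank test across the candidate set and all random sets.
Prioritized genes are finally evaluated against a pathogenicity gold
standard (fraction with pathogenic / likely-pathogenic assertions,
versus the same fraction over all candidates).

A fully synthetic resource generator emulates all twelve input resources
with configurable background vs. candidate annotation rates, so the
entire pipeline is testable without any database download.

## Worked example

Generate a synthetic bundle (3000-gene universe, 200 candidates, rates
taken from the motivating study's comparison table) and run the full
pipeline against 1000 random sets:

```
$ genepriority simulate --seed 42 --out demo/bundle
wrote bundle (3000 genes, 200 candidates) to demo/bundle
$ genepriority run-all --bundle demo/bundle --seed 42 --sets 1000 --out demo/report
prioritized 5 of 200 candidates; wrote 9 files to demo/report
```

`demo/report/category_tests.tsv` then holds one row per category in the
familiar table layout (values abbreviated):

| attribute | observed_n | expected_mean | chi2 | p | p_adj |
|---|---|---|---|---|---|
| brain_expressed | 182 | 168.84 | 6.10 | 1.35e-2 | 2.17e-2 |
| mouse_trait | 24 | 15.34 | 4.70 | 3.02e-2 | 4.03e-2 |
| tclin | 25 | 7.05 | 44.83 | 2.15e-11 | 8.61e-11 |
| tdark | 7 | 48.47 | 45.71 | 1.37e-11 | 8.61e-11 |
| acmg_network | 92 | 68.73 | 11.49 | 7.00e-4 | 1.40e-3 |
| all_attributes | 5 | 0.65 | 22.78 | 1.81e-6 | — |

Reading the first row: 182 of the 200 candidates are brain-expressed
versus 168.8 expected from random sets, giving χ² = 6.10, adjusted
*p* = 0.022 — the candidate list is enriched for every category except
Tbio/Tdark (Tdark, largely unstudied proteins, is depleted, as in the
motivating study). Five candidates carry evidence in all four
categories and are prioritized; `summary.json` records that all five
hold pathogenic or likely-pathogenic labels against a 52% candidate
baseline, and the expression contrast (Pillai = 0.080,
F₍₁₄,₂₈₃₅₎ = 17.7) localizes the planted signal to the pituitary.

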