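# Methods

## Pipeline model

The package implements a convergent-evidence prioritizer for disease
candidate gene lists. A candidate list (identifiers drawn from a
protein-coding gene universe) is annotated in four categories — brain
expression, mouse knockout trait, drug relevance, actionable-panel
interaction — and genes annotated in *all* categories are prioritized,
ordered by descending peak-region TPM with gene id as tie-break. The
stages run in a fixed order: expression flags → human and mouse process
overrepresentation → cross-species overlap → process-to-phenotype
mapping → knockout-trait flags → drug/pharmacogenomic flags →
interaction flags → profiles → random-set null → category proportion
tests → multivariate expression contrast → connection-count rank test →
prioritization → gold-standard evaluation. Everything downstream of a
seed is deterministic.

Key assumptions:

* **Gene identity** is a single opaque identifier string; symbols are
  display-only. Secondary tables covering genes outside the universe
  are trimmed with a logged count rather than rejected, because real
  resources cover different gene universes.
* **Drug relevance** is the union Tclin ∨ Tchem ∨ pharmacogenomic
  variant. This is the only intersection rule consistent with the
  motivating study's prioritized-gene table, where genes may lack a
  development level *or* a pharmacogenomic record but never both. An
  AND-variant is config-exposed (`require_drug_and_pgx`). Tbio and
  Tdark are annotated and reported but never contribute to
  prioritization.
* **"Either sex"** in knockout associations means any association row
  qualifies regardless of its sex value.
* A gene without a retained ortholog can never receive the trait flag —
  deliberately mirroring how untested knockouts (e.g. essential,
  embryonic-lethal genes) escape this annotation arm in practice.

## Statistical procedures

**One-proportion test.** χ² = n·(max(0, |x/n − p₀| − 1/(2n)))²/(p₀(1−p₀))
with one degree of freedom; the continuity correction is clamped at zero
so an exact match yields χ² = 0, p = 1. The 95% CI is the Wilson score
interval with continuity correction. Both choices are required to
reproduce the motivating study's printed statistics (all printed
chi-squares reproduce within ±0.1, all printed 2-dp CIs exactly; the
uncorrected statistic gives ≈12.5 where 11.30 is printed). The expected
proportion p₀ is the null mean count divided by the set size.

**Random-set null.** K (default 1000) sets of n distinct protein-coding
genes, uniform within set; genes recur freely across sets. "Allowing
for replacement" is read as across-set reuse — an individual *set* holds
distinct genes, since a multiset would deflate annotation proportions —
with the literal multiset reading available via `within_replacement`.
Null means/sds use the per-set annotation counts (sample sd, ddof = 1).

**Multiple testing.** The eight per-category raw p-values are
Benjamini–Hochberg adjusted together; the all-categories intersection
test is reported without adjustment (as in the motivating study's
table). Enrichment selection is Bonferroni at α = 0.05/n, boundary
inclusive. "Number of nodes tested" n defaults to every term meeting
the minimum annotated-size threshold (`n_tested_mode="min_size"`); the
alternative — only terms with ≥ 1 study gene — is config-exposed
because the phrase is ambiguous in the source material.

**Parent–child overrepresentation.** For term t with propagated gene
set G(t), the reference population is the union of the parents'
propagated sets (intersection config-exposed; union is the cited
implementation's default joining rule), the universe for roots. The
p-value is the upper hypergeometric tail P(X ≥ k) with M = |P|,
K = |G(t)|, m = |study ∩ P|, k = |study ∩ G(t)|. Terms below
`min_term_size` (default 1) or with zero study genes are skipped. With
a flat ontology and a fully annotated universe this reduces exactly to
the classic one-sided Fisher/hypergeometric test — a property the test
suite asserts, alongside exhaustive-enumeration checks on 10-gene
instances. No additional elim/weight decorrelation is implemented: the
conditional construction itself is the decorrelation.

**Expression contrast.** Two-group MANOVA on per-gene region-wise
log₂(TPM+1) vectors: candidates versus the distinct union of
random-set genes with candidates excluded (a disjoint two-group design;
pooling the multiset of K×n draws would only duplicate rows). Pillai's
trace V is converted by its standard F approximation, which for two
groups is exact and coincides with Hotelling's T² F — asserted against
an independently computed T² in the tests. Per-region univariate F
tests follow, BH-adjusted. A singular total-SSCP matrix raises with
advice to reduce regions. The motivating study's printed MANOVA
degrees of freedom cannot be reconstructed from its text; its printed
F/Pillai values are therefore not reproduction targets, and the
contrast here is the package's own design.

**Connection counts.** Kruskal–Wallis H (tie-corrected) across the
candidate set and all K random sets on per-gene counts of distinct
actionable partners at qualifying confidence; all-identical input
returns H = 0, p = 1. The interaction-confidence threshold defaults to
0.4, the "medium confidence" convention of the usual interaction
resource (config-exposed; the source material states none).

## Synthetic resource generator

The generator emulates the twelve input resources with per-gene
independent Bernoulli category flags: candidate genes at the candidate
rates, all other coding genes at the background rates. Default rates
are the motivating study's observed proportions (e.g. brain expression
0.846 background vs 0.901 candidate; Tdark 0.265 vs 0.053 — a planted
*depletion*). Development levels are drawn categorically so exactly one
level exists per gene while preserving the per-level marginal rates.
Flags are then *realized* through the emitted files:

* **Expression**: log₂ TPM ~ Normal(μ_region, σ = 1) with μ_region ~
  Normal(2, 1), producing realistic spreads around the 0.5-TPM
  threshold; flagged genes falling entirely below the threshold have
  their peak region resampled just above it, unflagged genes are
  clamped below. Candidate genes receive a +1 log₂ shift (2-fold) in a
  designated region (pituitary by default), large enough for the
  per-region contrast to localize the signal reliably at default sizes.
* **Ontologies**: rooted random DAGs; every non-root term draws 1–2
  parents among earlier terms, so any prefix of the term order is
  ancestor-closed, and the human/mouse process ontologies are realized
  as prefixes of one shared term order (enrichment must intersect on a
  shared namespace, as with the real process ontology). The phenotype
  DAG has disjoint top-level branches, three designated and the rest
  decoys.
* **Planted enrichment**: a configurable number of *leaf* process terms
  (default 6) are annotated in candidates at 0.5 versus 0.05 background;
  all other terms at a 0.05 baseline. Leaves are essential: a term with
  descendants has its propagated set flooded by baseline-annotated
  genes, which destroys the parent–child contrast the scenario is meant
  to exhibit. The 0.5 rate keeps the mouse-side test at high power —
  the ortholog filter roughly halves the mouse study — so the planted
  terms survive both species' Bonferroni selections and their overlap
  in essentially every seed (30/30 in validation). Each enriched term
  is cross-mapped (distance 1) to a phenotype term under a designated
  top-level branch; decoy mappings from non-enriched terms point at
  decoy branches, plus one distance-2 record that must be ignored.
* **Orthologs/knockouts**: trait-flagged genes always receive a passing
  prediction (support ≥ 2, best both directions) and ≥ 1 association
  with p = α·Beta(0.5, 5) ≤ 0.05 on a designated branch; unflagged
  genes receive failing predictions, passing predictions with null
  associations (p > 0.05 on-branch, or small p off-branch), or no
  prediction — so the filter and the branch test are exercised on both
  sides. Only confidently mapped orthologs inherit candidate-level
  annotation rates (a failing prediction is most likely a wrong
  mapping; letting it inherit candidate biology measurably diluted the
  mouse-side reference population).
* **Network**: flagged genes get 1+Poisson(1) partners on the
  59-gene actionable panel at confidence ≥ 0.4; sub-threshold panel
  contacts and a background of off-panel edges exercise the cut-off.
  Because satisfying edges between two panel members can flag a partner
  the Bernoulli draw left unflagged, the generator re-derives *realized*
  flags from the final edge list by direct scan and records both planted
  and realized flags in a `truth` side table; recovery tests compare
  against realized flags.
* **Labels**: pathogenic/likely-pathogenic at rate 0.78 for genes whose
  realized flags span all categories, 0.509 otherwise (the motivating
  study's prioritized and baseline prevalences).

What the generator does **not** emulate: co-annotation correlation
between categories or between process terms, linkage of drug levels to
network degree, and real expression covariance across regions. Passing
tests therefore demonstrate that the pipeline's arithmetic, filters and
calibration are correct under independence — not that the effect sizes
of any real disorder are recoverable.

## Numerical and design choices

* p₀ ∈ {0, 1} is rejected; categories with degenerate null means are
  skipped with a warning rather than tested.
* Expression max-region ties break by region-name order; ortholog
  ties keep the highest support count, then the lexicographically
  smallest target.
* Table outputs are written with `%.17g` floats and reloaded with
  round-trip parsing, so a bundle or report round-trips bit-exactly and
  repeated runs are byte-identical.
* Type-I calibration of the category tests is checked at
  study-equivalent size (956 of 19 000 coding genes — the protein-coding
  genome scale): at small desk-scale expected counts the continuity
  correction makes the test conservative below the nominal level by
  design, which is a property of the statistic, not an error. Measured
  per-category type-I error at study scale is 0.02–0.05 at α = 0.05.
* Default problem sizes used in the test suite (universe 3000,
  200 candidates, K ≤ 1000, 60 process terms) keep a complete
  end-to-end run under a second; the scale knobs all live in
  `ScenarioConfig`/`RunConfig`.

## Known limitations

* The parent–child conditioning assumes propagated annotation closure;
  annotations to terms missing from the ontology are fatal rather than
  skipped.
* Only `is_a` relations are honored in OBO input; other relationship
  types and evidence codes are out of scope.
* The prioritizer reports overlap with the actionable panel but neither
  requires nor forbids it, mirroring the observational stance of the
  motivating study.
* Database-snapshot-dependent headline counts of the motivating study
  (956 candidates, 861 expressed, 18 prioritized, 225/258/200
  overrepresented processes) are inherently irreproducible from
  synthetic data and are exercised only structurally.
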