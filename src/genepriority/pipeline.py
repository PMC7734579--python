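"""End-to-end orchestration: annotate, test against the null, prioritize.

Stage order follows the annotation pipeline: expression flags -> human and
mouse process overrepresentation -> cross-species overlap -> process-to-
phenotype mapping -> knockout-trait flags -> drug/pharmacogenomic flags ->
actionable-interaction flags -> per-gene profiles -> random-set null ->
per-category proportion tests -> multivariate expression contrast ->
connection-count rank test -> prioritization -> gold-standard evaluation.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, nullmodel, ontology
from .annotate import AnnotationProfile
from .nullmodel import ExpressionContrast, NullDistribution, ProportionTestResult
from .ontology import EnrichmentResult
from .resources import ResourceBundle

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PrioritizationReport",
    "GoldStandardSummary",
    "prioritize",
    "evaluate_gold_standard",
    "run_pipeline",
    "write_report",
]


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults follow the motivating study."""

    tpm_threshold: float = 0.5
    ko_alpha: float = 0.05
    enrichment_alpha: float = 0.05
    min_term_size: int = 1
    parent_join: str = "union"
    n_tested_mode: str = "min_size"       # or "nonzero_study"
    min_confidence: float = 0.4
    n_random_sets: int = 1000
    within_replacement: bool = False
    continuity: bool = True
    require_drug_and_pgx: bool = False

    def __post_init__(self) -> None:
        if self.n_tested_mode not in ("min_size", "nonzero_study"):
            raise ValueError("n_tested_mode must be 'min_size' or 'nonzero_study'")
        if self.n_random_sets < 1:
            raise ValueError("need at least one random set")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class GoldStandardSummary:
    """Pathogenic/likely-pathogenic prevalence among prioritized vs all candidates."""

    n_prioritized: int
    n_pathogenic: int
    proportion: float | None
    baseline_n: int
    baseline_pathogenic: int
    baseline_proportion: float | None

    @property
    def enrichment_ratio(self) -> float | None:
        if not self.proportion or not self.baseline_proportion:
            return None
        return self.proportion / self.baseline_proportion


@dataclass
class PrioritizationReport:
    prioritized: list[AnnotationProfile]
    profiles: list[AnnotationProfile]               # all candidate genes
    category_tests: list[ProportionTestResult]
    enrichment_human: list[EnrichmentResult]
    enrichment_mouse: list[EnrichmentResult]
    overlap_terms: frozenset[str]
    mp_terms: frozenset[str]
    top_level_terms: frozenset[str]
    expression: ExpressionContrast
    connection_H: float
    connection_p: float
    gold_standard: GoldStandardSummary
    null: NullDistribution
    n_candidates_on_actionable: int
    n_prioritized_on_actionable: int
    seed: int


def prioritize(profiles: list[AnnotationProfile]) -> list[AnnotationProfile]:
    """Genes annotated in every category, by descending peak TPM then id."""
    chosen = [p for p in profiles if p.all_categories]
    return sorted(chosen, key=lambda p: (-p.max_tpm, p.gene))


def evaluate_gold_standard(
    prioritized: list[str],
    all_candidates: list[str],
    labels: pd.DataFrame,
) -> GoldStandardSummary:
    """Count pathogenic/likely-pathogenic genes among prioritized and candidates."""
    pathogenic = frozenset(
        labels.loc[labels["label"].isin(["pathogenic", "likely_pathogenic"]), "gene"]
    )
    n_pri = len(prioritized)
    n_pri_path = sum(1 for g in prioritized if g in pathogenic)
    n_base = len(all_candidates)
    n_base_path = sum(1 for g in all_candidates if g in pathogenic)
    return GoldStandardSummary(
        n_prioritized=n_pri,
        n_pathogenic=n_pri_path,
        proportion=(n_pri_path / n_pri) if n_pri else None,
        baseline_n=n_base,
        baseline_pathogenic=n_base_path,
        baseline_proportion=(n_base_path / n_base) if n_base else None,
    )


def run_pipeline(bundle: ResourceBundle, config: RunConfig | None = None, seed: int = 0) -> PrioritizationReport:
    """Execute every stage on a loaded bundle; deterministic given ``seed``."""
    cfg = config or RunConfig()
    coding = bundle.universe.coding_ids
    coding_set = frozenset(coding)
    candidates = [g for g in bundle.candidates if g in coding_set]
    if len(candidates) < len(bundle.candidates):
        logger.warning(
            "dropped %d non-protein-coding candidate genes",
            len(bundle.candidates) - len(candidates),
        )

    # expression flags for every coding gene (random sets need them too)
    expr_flags = annotate.flag_expression(bundle.expression, coding, cfg.tpm_threshold)

    # process overrepresentation, human then mouse orthologs
    ann_h = ontology.propagate(bundle.ontology_human, bundle.annotations_human)
    res_h = ontology.parent_child_test(
        candidates, coding, bundle.ontology_human, ann_h, cfg.min_term_size, cfg.parent_join
    )
    n_h = (
        ontology.n_testable_terms(coding, bundle.ontology_human, ann_h, cfg.min_term_size)
        if cfg.n_tested_mode == "min_size"
        else len(res_h)
    )
    sig_h = ontology.bonferroni_select(res_h, cfg.enrichment_alpha, n_h)

    ortho_map = annotate.filter_orthologs(bundle.orthologs)
    mouse_universe = bundle.mouse_genes
    mouse_study = sorted({ortho_map[g] for g in candidates if g in ortho_map})
    ann_m = ontology.propagate(bundle.ontology_mouse, bundle.annotations_mouse)
    res_m = ontology.parent_child_test(
        mouse_study, mouse_universe, bundle.ontology_mouse, ann_m, cfg.min_term_size, cfg.parent_join
    )
    n_m = (
        ontology.n_testable_terms(mouse_universe, bundle.ontology_mouse, ann_m, cfg.min_term_size)
        if cfg.n_tested_mode == "min_size"
        else len(res_m)
    )
    sig_m = ontology.bonferroni_select(res_m, cfg.enrichment_alpha, n_m)

    overlap = ontology.cross_species_overlap(sig_h, sig_m)
    mp_terms, top_level = ontology.map_to_phenotype_terms(overlap, bundle.xmap, bundle.ontology_mp)

    phen_flags = annotate.flag_phenotype(
        coding, ortho_map, bundle.phenotypes, top_level, bundle.ontology_mp, cfg.ko_alpha
    )
    drug_pgx = annotate.flag_drug_and_pgx(coding, bundle.drug_targets, bundle.pgx)
    degrees = annotate.flag_acmg_interactions(
        bundle.network, coding, bundle.actionable, cfg.min_confidence
    )
    all_profiles = annotate.build_profiles(
        coding, expr_flags, phen_flags, drug_pgx, degrees, cfg.require_drug_and_pgx
    )
    by_gene = {p.gene: p for p in all_profiles}
    cand_profiles = [by_gene[g] for g in candidates]

    # random-set null and the category proportion tests
    sets = nullmodel.sample_random_sets(
        bundle.universe, len(candidates), cfg.n_random_sets, seed, cfg.within_replacement
    )
    flags = nullmodel.category_flag_frame(all_profiles)
    null = nullmodel.build_null(flags, sets)
    tests = nullmodel.category_tests(cand_profiles, null, cfg.continuity)

    contrast = nullmodel.expression_contrast(bundle.expression, candidates, sets)

    degree_series = pd.Series({p.gene: p.acmg_degree for p in all_profiles})
    cand_degrees = degree_series[candidates].to_numpy()
    random_degrees = [degree_series[list(s)].to_numpy() for s in sets]
    H, p_kw = nullmodel.connection_count_test(cand_degrees, random_degrees)

    chosen = prioritize(cand_profiles)
    gold = evaluate_gold_standard([p.gene for p in chosen], candidates, bundle.labels)

    act = frozenset(bundle.actionable)
    return PrioritizationReport(
        prioritized=chosen,
        profiles=cand_profiles,
        category_tests=tests,
        enrichment_human=res_h,
        enrichment_mouse=res_m,
        overlap_terms=overlap,
        mp_terms=mp_terms,
        top_level_terms=top_level,
        expression=contrast,
        connection_H=H,
        connection_p=p_kw,
        gold_standard=gold,
        null=null,
        n_candidates_on_actionable=sum(1 for g in candidates if g in act),
        n_prioritized_on_actionable=sum(1 for p in chosen if p.gene in act),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# report output


def _enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "name": [r.name for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "m": [r.m for r in results],
            "M": [r.M for r in results],
            "p": [r.p_value for r in results],
            "significant": [int(r.significant) for r in results],
        }
    )


def write_report(report: PrioritizationReport, out_dir: Path) -> list[Path]:
    """Write one TSV per results table plus a structured summary.

    Re-running with the same inputs reproduces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    save(nullmodel.category_tests_frame(report.category_tests), "category_tests.tsv")
    save(_enrichment_frame(report.enrichment_human), "enrichment_human.tsv")
    save(_enrichment_frame(report.enrichment_mouse), "enrichment_mouse.tsv")
    save(pd.DataFrame({"term": sorted(report.overlap_terms)}), "enrichment_overlap.tsv")
    save(annotate.profiles_frame(report.profiles), "annotations.tsv")
    save(annotate.profiles_frame(report.prioritized), "prioritized_genes.tsv")
    save(report.expression.per_region, "expression_regions.tsv")
    save(report.null.to_frame(), "null_counts.tsv")

    gs = report.gold_standard
    summary = {
        "n_candidates": len(report.profiles),
        "n_prioritized": len(report.prioritized),
        "prioritized_genes": [p.gene for p in report.prioritized],
        "overlap_terms": sorted(report.overlap_terms),
        "mapped_phenotype_terms": sorted(report.mp_terms),
        "top_level_phenotype_terms": sorted(report.top_level_terms),
        "expression_contrast": {
            "pillai": report.expression.pillai,
            "F": report.expression.F,
            "df1": report.expression.df1,
            "df2": report.expression.df2,
            "p": report.expression.p,
        },
        "connection_count_test": {"H": report.connection_H, "p": report.connection_p},
        "gold_standard": {
            "n_prioritized": gs.n_prioritized,
            "n_pathogenic": gs.n_pathogenic,
            "proportion": gs.proportion,
            "baseline_n": gs.baseline_n,
            "baseline_pathogenic": gs.baseline_pathogenic,
            "baseline_proportion": gs.baseline_proportion,
        },
        "candidates_on_actionable_panel": report.n_candidates_on_actionable,
        "prioritized_on_actionable_panel": report.n_prioritized_on_actionable,
        "seed": report.seed,
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
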