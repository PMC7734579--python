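"""Per-gene evidence flags for each pipeline category.

Four evidence categories drive prioritization:

* brain expression — TPM >= threshold (default 0.5) in at least one region;
* mouse trait — a retained one-to-one ortholog whose knockout shows an
  association (p <= 0.05, either sex) to a phenotype term descending from a
  top-level phenotype term linked to an overrepresented process;
* drug relevance — an approved-drug target (Tclin), a chemically tractable
  target (Tchem), or a literature-significant pharmacogenomic variant;
* actionable-panel interaction — at least one direct protein interaction
  (confidence >= threshold) with a product of a clinically actionable gene.

Tbio and Tdark development levels are annotated and reported but never
contribute to prioritization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationProfile",
    "flag_expression",
    "filter_orthologs",
    "flag_phenotype",
    "flag_drug_and_pgx",
    "flag_acmg_interactions",
    "build_profiles",
    "profiles_frame",
]


@dataclass
class AnnotationProfile:
    """One gene's boolean evidence vector plus supporting detail."""

    gene: str
    brain_expressed: bool
    max_region: str | None
    max_tpm: float
    mouse_trait: bool
    trait_terms: tuple[tuple[str, str], ...]  # (top-level term, specific trait term)
    drug_level: str                            # Tclin/Tchem/Tbio/Tdark/none
    pgx: bool
    guidelines: tuple[str, ...]
    acmg_interaction: bool
    acmg_degree: int
    all_categories: bool

    @property
    def drug_relevant(self) -> bool:
        return self.drug_level in ("Tclin", "Tchem") or self.pgx


def flag_expression(
    expression: pd.DataFrame,
    genes: Sequence[str],
    threshold: float = 0.5,
) -> dict[str, tuple[bool, str | None, float]]:
    """Expressed iff TPM >= threshold in >= 1 region (boundary inclusive).

    Returns gene -> (flag, region of maximal TPM, maximal TPM); ties are
    broken by region-name order.  Genes absent from the matrix are flagged
    False and logged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    cols = sorted(expression.columns)
    sub = expression.reindex(genes)[cols]
    missing = sub.index[sub.isna().all(axis=1)]
    if len(missing):
        logger.warning("expression: %d genes absent from matrix", len(missing))
    out: dict[str, tuple[bool, str | None, float]] = {}
    values = sub.to_numpy()
    for i, gene in enumerate(sub.index):
        row = values[i]
        if np.isnan(row).all():
            out[gene] = (False, None, 0.0)
            continue
        j = int(np.nanargmax(row))
        out[gene] = (bool(row[j] >= threshold), cols[j], float(row[j]))
    return out


def filter_orthologs(predictions: pd.DataFrame) -> dict[str, str]:
    """Retain high-rank ortholog predictions, one per source gene.

    Keeps pairs supported by >= 2 prediction tools with the best score in
    both forward and reverse mapping; among survivors for one source gene,
    the highest support count wins, ties broken by lexicographically
    smallest target.
    """
    ok = predictions[
        (predictions["support_count"] >= 2)
        & predictions["best_forward"]
        & predictions["best_reverse"]
    ]
    ok = ok.sort_values(
        ["source", "support_count", "target"], ascending=[True, False, True]
    ).drop_duplicates("source", keep="first")
    return dict(zip(ok["source"], ok["target"]))


def flag_phenotype(
    genes: Sequence[str],
    ortholog_map: Mapping[str, str],
    phenotypes: pd.DataFrame,
    top_level: Iterable[str],
    mp_dag: OntologyDAG,
    alpha: float = 0.05,
) -> dict[str, tuple[bool, tuple[tuple[str, str], ...]]]:
    """Knockout-trait flags via retained orthologs.

    A gene is flagged iff its retained ortholog has >= 1 association with
    p <= alpha (either sex) whose phenotype term descends from (or equals)
    a top-level term.  Genes without a retained ortholog are never flagged.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    tops = sorted(top_level)
    branch = {t: mp_dag.descendants(t) | {t} for t in tops}

    hits = phenotypes[phenotypes["p_value"] <= alpha]
    # term -> matching top-level terms, computed once per distinct term
    term_tops: dict[str, list[str]] = {}
    for term in hits["mp_term"].unique():
        term_tops[term] = [t for t in tops if term in branch[t]]
    by_mouse: dict[str, list[tuple[str, str]]] = {}
    for mouse_gene, term in zip(hits["gene"], hits["mp_term"]):
        for t in term_tops[term]:
            by_mouse.setdefault(mouse_gene, []).append((t, term))

    out: dict[str, tuple[bool, tuple[tuple[str, str], ...]]] = {}
    for gene in genes:
        target = ortholog_map.get(gene)
        pairs = by_mouse.get(target, []) if target else []
        out[gene] = (bool(pairs), tuple(sorted(set(pairs))))
    return out


def flag_drug_and_pgx(
    genes: Sequence[str],
    drug_targets: pd.DataFrame,
    pgx: pd.DataFrame,
) -> dict[str, tuple[str, bool, tuple[str, ...]]]:
    """Gene -> (development level or 'none', pgx flag, guideline ids).

    Only pharmacogenomic records marked significant contribute.
    """
    levels = dict(zip(drug_targets["gene"], drug_targets["level"]))
    sig = pgx[pgx["significant"]]
    guide: dict[str, set[str]] = {}
    for gene, gl in zip(sig["gene"], sig["guideline"]):
        guide.setdefault(gene, set())
        if isinstance(gl, str) and gl:
            guide[gene].add(gl)
    return {
        g: (levels.get(g, "none"), g in guide, tuple(sorted(guide.get(g, ()))))
        for g in genes
    }


def flag_acmg_interactions(
    network: pd.DataFrame,
    genes: Sequence[str],
    actionable: Iterable[str],
    min_confidence: float = 0.4,
) -> dict[str, int]:
    """Gene -> number of distinct actionable partners at qualifying confidence."""
    if not 0 <= min_confidence <= 1:
        raise ValueError("min_confidence must be in [0, 1]")
    act = frozenset(actionable)
    strong = network[network["confidence"] >= min_confidence]
    partners: dict[str, set[str]] = {}
    for a, b in zip(strong["protein_a"], strong["protein_b"]):
        if b in act:
            partners.setdefault(a, set()).add(b)
        if a in act:
            partners.setdefault(b, set()).add(a)
    return {g: len(partners.get(g, ())) for g in genes}


def build_profiles(
    genes: Sequence[str],
    expression_flags: Mapping[str, tuple[bool, str | None, float]],
    phenotype_flags: Mapping[str, tuple[bool, tuple]],
    drug_pgx: Mapping[str, tuple[str, bool, tuple[str, ...]]],
    acmg_degrees: Mapping[str, int],
    require_drug_and_pgx: bool = False,
) -> list[AnnotationProfile]:
    """Assemble per-gene profiles and the all-categories intersection flag.

    The intersection requires brain expression, a mouse trait, drug
    relevance (Tclin or Tchem level, or a significant pharmacogenomic
    variant — an AND of the two halves if ``require_drug_and_pgx``), and an
    actionable-panel interaction.  Deterministic order follows ``genes``.
    """
    missing = [
        g
        for g in genes
        if g not in expression_flags
        or g not in phenotype_flags
        or g not in drug_pgx
        or g not in acmg_degrees
    ]
    if missing:
        raise ValueError(f"stage outputs missing genes, e.g. {missing[:5]}")
    profiles = []
    for g in genes:
        expressed, region, tpm = expression_flags[g]
        trait, trait_terms = phenotype_flags[g]
        level, has_pgx, guidelines = drug_pgx[g]
        degree = int(acmg_degrees[g])
        druggable = level in ("Tclin", "Tchem")
        drug_ok = (druggable and has_pgx) if require_drug_and_pgx else (druggable or has_pgx)
        profiles.append(
            AnnotationProfile(
                gene=g,
                brain_expressed=expressed,
                max_region=region,
                max_tpm=tpm,
                mouse_trait=trait,
                trait_terms=trait_terms,
                drug_level=level,
                pgx=has_pgx,
                guidelines=guidelines,
                acmg_interaction=degree >= 1,
                acmg_degree=degree,
                all_categories=bool(expressed and trait and drug_ok and degree >= 1),
            )
        )
    return profiles


def profiles_frame(profiles: Sequence[AnnotationProfile]) -> pd.DataFrame:
    """Flat table of profiles (one row per gene, booleans as 0/1 detail kept)."""
    return pd.DataFrame(
        {
            "gene": [p.gene for p in profiles],
            "brain_expressed": [p.brain_expressed for p in profiles],
            "max_region": [p.max_region or "" for p in profiles],
            "max_tpm": [p.max_tpm for p in profiles],
            "mouse_trait": [p.mouse_trait for p in profiles],
            "trait_terms": [
                ";".join(f"{top}|{term}" for top, term in p.trait_terms) for p in profiles
            ],
            "drug_level": [p.drug_level for p in profiles],
            "pgx": [p.pgx for p in profiles],
            "guidelines": [";".join(p.guidelines) for p in profiles],
            "acmg_interaction": [p.acmg_interaction for p in profiles],
            "acmg_degree": [p.acmg_degree for p in profiles],
            "all_categories": [p.all_categories for p in profiles],
        }
    )
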