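"""Synthetic resource bundles with statistically controlled annotation rates.

The generator emulates the structure of the public resources the pipeline
consumes, so every stage is testable without any download.  Per-gene
category memberships are independent Bernoulli draws at a background rate
for ordinary genes and a (usually higher) rate for candidate genes; the
default rates are the observed random-set and candidate proportions of the
motivating study (e.g. 84.6% vs 90.1% brain-expressed).  Those planted
flags are then *realized* through the actual resource files: expression
values straddling the TPM threshold, ortholog predictions that pass or
fail the two-tool/best-both-directions filter, knockout associations
inside or outside the designated phenotype branches, drug development
levels, pharmacogenomic records, and interaction edges above or below the
confidence cut-off.

Ontologies are rooted random DAGs (every non-root term draws 1-2 parents
among earlier terms, so any prefix of the term order is ancestor-closed).
A configurable subset of process terms is enriched in candidates and
mapped (distance 1) to phenotype terms under designated top-level
branches, which is what lets the enrichment -> phenotype arm of the
pipeline recover the planted mouse-trait flags.

A ``truth`` side table records both the planted flags and the flags
realized by the emitted files (they differ only where satisfying
interaction edges between actionable genes induce extra qualifying
neighbors), so tests can measure recovery exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ontology import OntologyDAG
from .resources import GeneUniverse, ResourceBundle

__all__ = ["ScenarioConfig", "generate_bundle", "generate_null_scenario"]

#: brain regions profiled by the tissue-expression resource
DEFAULT_REGIONS = (
    "amygdala",
    "anterior cingulate cortex",
    "brodmann area 24",
    "caudate",
    "cerebellar hemisphere",
    "cerebellum",
    "frontal cortex",
    "hippocampus",
    "hypothalamus",
    "nucleus accumbens",
    "putamen",
    "spinal cord",
    "substantia nigra",
    "pituitary",
)

RATE_KEYS = (
    "brain_expressed",
    "mouse_trait",
    "tclin",
    "tchem",
    "tbio",
    "tdark",
    "pgx",
    "acmg_network",
)


def _default_background_rates() -> dict[str, float]:
    # random-set means over n = 956 from the motivating study's comparison table
    return {
        "brain_expressed": 0.846,
        "mouse_trait": 0.072,
        "tclin": 0.033,
        "tchem": 0.084,
        "tbio": 0.601,
        "tdark": 0.265,
        "pgx": 0.055,
        "acmg_network": 0.328,
    }


def _default_candidate_rates() -> dict[str, float]:
    # candidate-list proportions from the same table (note Tdark is depleted)
    return {
        "brain_expressed": 0.901,
        "mouse_trait": 0.092,
        "tclin": 0.118,
        "tchem": 0.155,
        "tbio": 0.643,
        "tdark": 0.053,
        "pgx": 0.130,
        "acmg_network": 0.497,
    }


@dataclass
class ScenarioConfig:
    """Knobs for one synthetic scenario.

    Probabilities must lie in [0, 1]; the candidate list is drawn from the
    protein-coding part of the universe.
    """

    universe_size: int = 3000
    candidate_size: int = 200
    n_regions: int = 14
    elevated_region: str | None = None          # default: pituitary if present, else last
    n_terms_human: int = 60
    n_terms_mouse: int = 60
    n_terms_mp: int = 40
    background_rates: dict[str, float] = field(default_factory=_default_background_rates)
    candidate_rates: dict[str, float] = field(default_factory=_default_candidate_rates)
    expression_elevation: float = 1.0           # log2 TPM shift in the elevated region
    pathogenic_rate_prioritized: float = 0.78
    pathogenic_rate_background: float = 0.509
    actionable_size: int = 59
    seed: int = 0
    # shape knobs (no distributional detail is prescribed by the study)
    noncoding_fraction: float = 0.05
    tpm_threshold: float = 0.5
    sigma_log2: float = 1.0
    mu_region_mean: float = 2.0
    mu_region_sd: float = 1.0
    n_enriched_terms: int = 6
    enriched_rate_candidate: float = 0.5
    enriched_rate_background: float = 0.05
    baseline_annotation_rate: float = 0.05
    ortholog_coverage: float = 0.8
    ko_alpha: float = 0.05
    n_mp_top_level: int = 5
    n_designated_top_level: int = 3
    background_edge_factor: float = 2.0
    min_confidence: float = 0.4

    def __post_init__(self) -> None:
        for name, rates in (("background_rates", self.background_rates),
                            ("candidate_rates", self.candidate_rates)):
            missing = set(RATE_KEYS) - set(rates)
            if missing:
                raise ValueError(f"{name} missing categories: {sorted(missing)}")
            for k, v in rates.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"{name}[{k}] = {v} outside [0, 1]")
        for name in (
            "noncoding_fraction", "enriched_rate_candidate", "enriched_rate_background",
            "baseline_annotation_rate", "ortholog_coverage", "ko_alpha",
            "pathogenic_rate_prioritized", "pathogenic_rate_background", "min_confidence",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.expression_elevation < 0:
            raise ValueError("expression_elevation must be >= 0")
        n_coding = self.universe_size - int(self.noncoding_fraction * self.universe_size)
        if self.candidate_size > n_coding:
            raise ValueError("candidate_size exceeds protein-coding universe size")
        if self.actionable_size > n_coding:
            raise ValueError("actionable_size exceeds protein-coding universe size")
        if self.n_designated_top_level >= self.n_mp_top_level:
            raise ValueError("need at least one non-designated top-level phenotype branch")
        if self.n_terms_mp < self.n_mp_top_level + self.n_designated_top_level:
            raise ValueError("phenotype ontology too small for the requested branches")
        for n in (self.universe_size, self.candidate_size, self.n_regions,
                  self.n_terms_human, self.n_terms_mouse, self.n_terms_mp):
            if n < 1:
                raise ValueError("sizes must be positive")

    @classmethod
    def from_yaml(cls, path: Path) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def generate_null_scenario(config: ScenarioConfig) -> ResourceBundle:
    """A bundle in which candidates are exchangeable with background genes.

    Candidate rates are replaced by the background rates and the regional
    expression elevation is removed; used for type-I-error calibration.
    """
    null_cfg = dataclasses.replace(
        config,
        candidate_rates=dict(config.background_rates),
        expression_elevation=0.0,
    )
    return generate_bundle(null_cfg)


# ---------------------------------------------------------------------------


def _random_dag(rng: np.random.Generator, n: int, prefix: str, name: str) -> tuple[list[str], list[tuple[str, str]]]:
    """Rooted random DAG: term i >= 1 draws 1-2 parents among earlier terms."""
    terms = [f"{prefix}:{i + 1:07d}" for i in range(n)]
    edges = []
    for i in range(1, n):
        n_par = 1 + int(rng.random() < 0.35 and i >= 2)
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        for p in parents:
            edges.append((terms[i], terms[int(p)]))
    return terms, edges


def _mp_dag(rng: np.random.Generator, cfg: ScenarioConfig) -> tuple[OntologyDAG, list[str], dict[str, list[str]]]:
    """Phenotype DAG with disjoint top-level branches.

    Returns the DAG, the ordered top-level terms, and branch membership
    (descendants including the top-level term itself).
    """
    n = cfg.n_terms_mp
    terms = [f"MP:{i + 1:07d}" for i in range(n)]
    root = terms[0]
    tops = terms[1 : cfg.n_mp_top_level + 1]
    edges = [(t, root) for t in tops]
    branch_members: dict[str, list[str]] = {t: [t] for t in tops}
    for i in range(cfg.n_mp_top_level + 1, n):
        top = tops[(i - cfg.n_mp_top_level - 1) % len(tops)]
        members = branch_members[top]
        parent = members[int(rng.integers(len(members)))]
        edges.append((terms[i], parent))
        if len(members) > 1 and rng.random() < 0.3:
            other = members[int(rng.integers(len(members)))]
            if other != parent:
                edges.append((terms[i], other))
        members.append(terms[i])
    names = {t: f"phenotype {i + 1}" for i, t in enumerate(terms)}
    names[root] = "mammalian phenotype"
    return OntologyDAG.from_edges(terms, edges, names), tops, branch_members


def generate_bundle(config: ScenarioConfig) -> ResourceBundle:
    """Generate a complete, validated resource bundle for one scenario."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- universe and candidate list -------------------------------------
    ids = [f"G{i + 1:05d}" for i in range(cfg.universe_size)]
    n_noncoding = int(cfg.noncoding_fraction * cfg.universe_size)
    noncoding = set(rng.choice(cfg.universe_size, size=n_noncoding, replace=False).tolist())
    coding_mask = np.array([i not in noncoding for i in range(cfg.universe_size)])
    universe = GeneUniverse(
        pd.DataFrame(
            {
                "id": ids,
                "symbol": [f"SYM{i + 1:05d}" for i in range(cfg.universe_size)],
                "protein_coding": coding_mask.astype(int),
            }
        )
    )
    coding = [g for g, ok in zip(ids, coding_mask) if ok]
    n_coding = len(coding)
    candidates = sorted(rng.choice(coding, size=cfg.candidate_size, replace=False).tolist())
    cand_set = frozenset(candidates)
    is_cand = np.array([g in cand_set for g in coding])

    # --- planted category flags ------------------------------------------
    def rate_vec(cat: str) -> np.ndarray:
        return np.where(is_cand, cfg.candidate_rates[cat], cfg.background_rates[cat])

    planted: dict[str, np.ndarray] = {}
    for cat in ("brain_expressed", "mouse_trait", "pgx", "acmg_network"):
        planted[cat] = rng.random(n_coding) < rate_vec(cat)
    # exactly one development level per gene: categorical draw whose marginal
    # rates match the per-level Bernoulli rates
    level_rates = np.stack([rate_vec(c) for c in ("tclin", "tchem", "tbio", "tdark")], axis=1)
    cum = np.cumsum(level_rates, axis=1)
    if (cum[:, -1] > 1).any():
        raise ValueError("development-level rates sum to more than 1")
    u = rng.random(n_coding)[:, None]
    level_idx = (u < cum).argmax(axis=1)
    level_idx[u[:, 0] >= cum[:, -1]] = -1
    levels = np.array(["Tclin", "Tchem", "Tbio", "Tdark"], dtype=object)
    drug_level = np.where(level_idx >= 0, levels[np.clip(level_idx, 0, 3)], "none")
    for j, cat in enumerate(("tclin", "tchem", "tbio", "tdark")):
        planted[cat] = level_idx == j

    # --- expression matrix ------------------------------------------------
    regions = list(DEFAULT_REGIONS[: cfg.n_regions])
    regions += [f"region {i + 1}" for i in range(len(regions), cfg.n_regions)]
    elevated = cfg.elevated_region or ("pituitary" if "pituitary" in regions else regions[-1])
    if elevated not in regions:
        raise ValueError(f"elevated_region {elevated!r} not among generated regions")
    mu = rng.normal(cfg.mu_region_mean, cfg.mu_region_sd, size=cfg.n_regions)
    log2tpm = rng.normal(mu, cfg.sigma_log2, size=(cfg.universe_size, cfg.n_regions))
    cand_rows = np.array([g in cand_set for g in ids])
    log2tpm[cand_rows, regions.index(elevated)] += cfg.expression_elevation
    # realize the planted expression flags around the TPM threshold
    log_thr = np.log2(cfg.tpm_threshold)
    coding_rows = np.flatnonzero(coding_mask)
    for row, flag in zip(coding_rows, planted["brain_expressed"]):
        vals = log2tpm[row]
        if flag and vals.max() < log_thr:
            vals[int(vals.argmax())] = log_thr + rng.exponential(1.0)
        elif not flag:
            high = vals >= log_thr
            if high.any():
                vals[high] = log_thr - rng.exponential(1.0, size=int(high.sum())) - 1e-9
    expression = pd.DataFrame(np.power(2.0, log2tpm), index=pd.Index(ids, name="id"), columns=regions)

    # --- ontologies --------------------------------------------------------
    n_go = max(cfg.n_terms_human, cfg.n_terms_mouse)
    go_terms, go_edges = _random_dag(rng, n_go, "GO", "process")
    go_names = {t: f"process {i + 1}" for i, t in enumerate(go_terms)}

    def prefix_dag(k: int) -> OntologyDAG:
        keep = set(go_terms[:k])
        return OntologyDAG.from_edges(
            go_terms[:k],
            [(c, p) for c, p in go_edges if c in keep and p in keep],
            {t: go_names[t] for t in go_terms[:k]},
        )

    ontology_human = prefix_dag(cfg.n_terms_human)
    ontology_mouse = prefix_dag(cfg.n_terms_mouse)
    ontology_mp, mp_tops, branch_members = _mp_dag(rng, cfg)
    designated = mp_tops[: cfg.n_designated_top_level]
    decoy_tops = mp_tops[cfg.n_designated_top_level :]

    # enrichment is planted at leaf terms: a term with descendants (or an
    # enriched ancestor/descendant) has its propagated gene set flooded by
    # baseline-annotated genes, which dilutes the parent-child contrast the
    # scenario is supposed to exhibit
    full_dag = prefix_dag(n_go)
    shared = min(cfg.n_terms_human, cfg.n_terms_mouse)
    lo = max(1, shared // 2)
    order = [int(i) for i in rng.permutation(np.arange(lo, shared))]
    enriched_terms: list[str] = []
    blocked: set[str] = set()
    for leaves_only in (True, False):
        for i in order:
            t = go_terms[i]
            if t in blocked or t in enriched_terms:
                continue
            if leaves_only and full_dag.descendants(t):
                continue
            enriched_terms.append(t)
            blocked |= full_dag.ancestors(t) | full_dag.descendants(t)
            if len(enriched_terms) == cfg.n_enriched_terms:
                break
        if len(enriched_terms) == cfg.n_enriched_terms:
            break
    enriched_terms.sort()

    # --- orthologs (generated before annotations so mouse genes exist) ----
    mouse_of = {g: f"MUS{g[1:]}" for g in coding}
    ortho_rows: list[tuple[str, str, int, int, int]] = []
    has_pass = np.zeros(n_coding, dtype=bool)
    for i, g in enumerate(coding):
        trait = planted["mouse_trait"][i]
        if trait:
            ortho_rows.append((g, mouse_of[g], int(rng.integers(2, 4)), 1, 1))
            has_pass[i] = True
        elif rng.random() < cfg.ortholog_coverage:
            mode = rng.random()
            if mode < 0.25:
                ortho_rows.append((g, mouse_of[g], 1, 1, 1))
            elif mode < 0.5:
                flip = rng.random() < 0.5
                ortho_rows.append((g, mouse_of[g], int(rng.integers(2, 4)), int(flip), int(not flip)))
            else:
                ortho_rows.append((g, mouse_of[g], int(rng.integers(2, 4)), 1, 1))
                has_pass[i] = True
        # occasional competing low-support prediction to exercise the tie rules
        if ortho_rows and ortho_rows[-1][0] == g and rng.random() < 0.1:
            ortho_rows.append((g, f"MUSALT{g[1:]}", 1, 1, 1))
    orthologs = pd.DataFrame(
        ortho_rows, columns=["source", "target", "support_count", "best_forward", "best_reverse"]
    )
    for c in ("best_forward", "best_reverse"):
        orthologs[c] = orthologs[c].astype(bool)

    # --- direct annotations (human and mouse share the term namespace) ----
    enriched_set = set(enriched_terms)

    def draw_annotations(genes: list[str], cand_flags: np.ndarray, terms: list[str]) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for t in terms[1:]:  # skip the root
            if t in enriched_set:
                rate = np.where(cand_flags, cfg.enriched_rate_candidate, cfg.enriched_rate_background)
            else:
                rate = np.full(len(genes), cfg.baseline_annotation_rate)
            hits = rng.random(len(genes)) < rate
            for g in np.asarray(genes, dtype=object)[hits]:
                out.setdefault(g, set()).add(t)
        return {g: frozenset(ts) for g, ts in sorted(out.items())}

    annotations_human = draw_annotations(coding, is_cand, go_terms[: cfg.n_terms_human])
    mouse_genes = sorted(set(orthologs["target"]))
    src_of = {}
    for r in ortho_rows:
        src_of.setdefault(r[1], r[0])
    # only confidently mapped orthologs inherit candidate biology: a
    # prediction that fails the support/best-score filter is most likely a
    # wrong mapping, so its mouse gene is annotated at background rates
    pass_targets = {mouse_of[g] for g, ok in zip(coding, has_pass) if ok}
    mouse_cand = np.array(
        [m in pass_targets and src_of.get(m, "") in cand_set for m in mouse_genes]
    )
    annotations_mouse = draw_annotations(mouse_genes, mouse_cand, go_terms[: cfg.n_terms_mouse])

    # --- cross-ontology map and knockout phenotype associations -----------
    desc_pool = {t: sorted(branch_members[t]) for t in mp_tops}
    xmap_rows = []
    for j, t in enumerate(enriched_terms):
        top = designated[j % len(designated)]
        pool = desc_pool[top]
        xmap_rows.append((t, pool[int(rng.integers(len(pool)))], 1))
    non_enriched_pool = [
        t for t in go_terms[1:shared]
        if t not in enriched_set and not (ontology_human.ancestors(t) & enriched_set)
        and not (ontology_human.descendants(t) & enriched_set)
    ]
    for t in rng.choice(non_enriched_pool, size=min(3, len(non_enriched_pool)), replace=False):
        top = decoy_tops[int(rng.integers(len(decoy_tops)))]
        pool = desc_pool[top]
        xmap_rows.append((t, pool[int(rng.integers(len(pool)))], 1))
    if len(non_enriched_pool) > 3:  # a distance-2 record that must be ignored
        xmap_rows.append((non_enriched_pool[0], desc_pool[decoy_tops[0]][0], 2))
    xmap = pd.DataFrame(xmap_rows, columns=["source_term", "target_term", "distance"])

    designated_terms = sorted(set().union(*(branch_members[t] for t in designated)))
    decoy_terms = sorted(set().union(*(branch_members[t] for t in decoy_tops)))
    sexes = np.array(["female", "male", "both"], dtype=object)
    phen_rows = []
    for i, g in enumerate(coding):
        target = mouse_of[g]
        if planted["mouse_trait"][i]:
            for _ in range(1 + int(rng.poisson(0.7))):
                term = designated_terms[int(rng.integers(len(designated_terms)))]
                p = float(np.clip(cfg.ko_alpha * rng.beta(0.5, 5.0), 1e-12, cfg.ko_alpha))
                phen_rows.append((target, term, p, sexes[int(rng.integers(3))]))
        elif has_pass[i] and rng.random() < 0.5:
            # null association: either not significant, or significant but
            # outside every designated phenotype branch
            if rng.random() < 0.5:
                term = designated_terms[int(rng.integers(len(designated_terms)))]
                p = float(rng.uniform(cfg.ko_alpha + 0.01, 1.0))
            else:
                term = decoy_terms[int(rng.integers(len(decoy_terms)))]
                p = float(np.clip(cfg.ko_alpha * rng.beta(0.5, 5.0), 1e-12, cfg.ko_alpha))
            phen_rows.append((target, term, p, sexes[int(rng.integers(3))]))
    phenotypes = pd.DataFrame(phen_rows, columns=["gene", "mp_term", "p_value", "sex"])

    # --- drug targets and pharmacogenomics --------------------------------
    drug_targets = pd.DataFrame(
        [(g, lvl) for g, lvl in zip(coding, drug_level) if lvl != "none"],
        columns=["gene", "level"],
    )
    pgx_rows = []
    for i, g in enumerate(coding):
        if planted["pgx"][i]:
            for _ in range(1 + int(rng.random() < 0.3)):
                pgx_rows.append((g, f"rs{int(rng.integers(10**6)):06d}", 1, f"PA{int(rng.integers(10**5)):05d}"))
        elif rng.random() < 0.1:
            pgx_rows.append((g, f"rs{int(rng.integers(10**6)):06d}", 0, ""))
    pgx = pd.DataFrame(pgx_rows, columns=["gene", "variant", "significant", "guideline"])
    pgx["significant"] = pgx["significant"].astype(bool)

    # --- actionable panel and interaction network --------------------------
    actionable = sorted(rng.choice(coding, size=cfg.actionable_size, replace=False).tolist())
    act_set = frozenset(actionable)
    act_arr = np.asarray(actionable, dtype=object)
    edge_conf: dict[tuple[str, str], float] = {}

    def add_edge(a: str, b: str, conf: float) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        edge_conf[key] = max(edge_conf.get(key, 0.0), conf)

    for i, g in enumerate(coding):
        if planted["acmg_network"][i]:
            d = 1 + int(rng.poisson(1.0))
            pool = act_arr[act_arr != g]
            partners = rng.choice(pool, size=min(d, len(pool)), replace=False)
            for p in partners:
                add_edge(g, str(p), float(rng.uniform(cfg.min_confidence, 1.0)))
        elif rng.random() < 0.1:
            # sub-threshold contact with the panel: must not flag the gene
            p = str(act_arr[int(rng.integers(len(act_arr)))])
            if p != g:
                add_edge(g, p, float(rng.uniform(0.0, cfg.min_confidence * 0.999)))
    non_act = [g for g in coding if g not in act_set]
    n_bg = int(cfg.background_edge_factor * cfg.universe_size)
    pairs = rng.integers(0, len(non_act), size=(n_bg, 2))
    confs = rng.random(n_bg)
    for (a, b), c in zip(pairs, confs):
        if a != b:
            add_edge(non_act[int(a)], non_act[int(b)], float(c))
    network = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(edge_conf.items())],
        columns=["protein_a", "protein_b", "confidence"],
    )

    # realized actionable-interaction flags, by direct scan of the edges
    realized_acmg = {g: False for g in coding}
    for (a, b), c in edge_conf.items():
        if c >= cfg.min_confidence:
            if b in act_set and a in realized_acmg:
                realized_acmg[a] = True
            if a in act_set and b in realized_acmg:
                realized_acmg[b] = True
    realized_acmg_arr = np.array([realized_acmg[g] for g in coding])

    # --- pathogenicity labels ----------------------------------------------
    drug_relevant = planted["tclin"] | planted["tchem"] | planted["pgx"]
    all_cats = planted["brain_expressed"] & planted["mouse_trait"] & drug_relevant & realized_acmg_arr
    label_rows = []
    for i, g in enumerate(coding):
        rate = cfg.pathogenic_rate_prioritized if all_cats[i] else cfg.pathogenic_rate_background
        if rng.random() < rate:
            label_rows.append((g, "pathogenic" if rng.random() < 0.5 else "likely_pathogenic"))
        elif rng.random() < 0.3:
            label_rows.append((g, "other"))
    labels = pd.DataFrame(label_rows, columns=["gene", "label"])

    truth = pd.DataFrame(
        {
            "gene": coding,
            "is_candidate": is_cand,
            **{f"planted_{c}": planted[c] for c in RATE_KEYS},
            "realized_acmg_network": realized_acmg_arr,
            "all_categories": all_cats,
        }
    )

    return ResourceBundle(
        universe=universe,
        candidates=candidates,
        expression=expression,
        ontology_human=ontology_human,
        ontology_mouse=ontology_mouse,
        ontology_mp=ontology_mp,
        annotations_human=annotations_human,
        annotations_mouse=annotations_mouse,
        orthologs=orthologs,
        phenotypes=phenotypes,
        drug_targets=drug_targets,
        pgx=pgx,
        network=network,
        actionable=actionable,
        labels=labels,
        xmap=xmap,
        truth=truth,
    )
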