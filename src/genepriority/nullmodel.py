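"""Random-gene-set null distribution and the pipeline's statistical tests.

Every annotation category is compared against K (default 1000) random sets
of protein-coding genes of the same size as the candidate list.  Genes may
recur across sets; each individual set holds distinct genes (a
``within_replacement`` switch implements the literal multiset reading).
The observed candidate proportion is tested against the null-mean
proportion with a continuity-corrected one-proportion chi-square test and
a Wilson score interval with continuity correction; raw p-values across
the reported categories are Benjamini-Hochberg adjusted.  Expression is
compared with a two-group multivariate contrast (Pillai's trace) over
region-wise log2(TPM+1) vectors, and actionable-interaction counts with a
Kruskal-Wallis rank test across the candidate set and every random set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import AnnotationProfile
from .resources import GeneUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "NullDistribution",
    "ProportionTestResult",
    "ExpressionContrast",
    "sample_random_sets",
    "one_proportion_chisq",
    "wilson_interval",
    "bh_adjust",
    "category_flag_frame",
    "build_null",
    "category_tests",
    "expression_contrast",
    "connection_count_test",
]

#: the reported annotation attributes, in table order
CATEGORIES = (
    "brain_expressed",
    "mouse_trait",
    "tclin",
    "tchem",
    "tbio",
    "tdark",
    "pgx",
    "acmg_network",
)
ALL_ATTRIBUTES = "all_attributes"


@dataclass
class NullDistribution:
    """Per-category annotation counts over K random gene sets."""

    counts: dict[str, np.ndarray]
    n: int                       # genes per set
    K: int                       # number of sets

    def mean(self, category: str) -> float:
        return float(np.mean(self.counts[category]))

    def sd(self, category: str) -> float:
        return float(np.std(self.counts[category], ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts)


@dataclass
class ProportionTestResult:
    category: str
    x: int
    n: int
    p0: float
    chi2: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: float | None = None
    expected_mean: float | None = None
    expected_sd: float | None = None


@dataclass
class ExpressionContrast:
    pillai: float
    F: float
    df1: int
    df2: int
    p: float
    per_region: pd.DataFrame     # region, F, p, p_adj


def sample_random_sets(
    universe: GeneUniverse,
    n: int,
    K: int,
    seed: int | np.random.Generator = 0,
    within_replacement: bool = False,
) -> list[list[str]]:
    """K uniform random sets of n protein-coding genes.

    Genes recur freely across sets; within a set genes are distinct unless
    ``within_replacement`` asks for the literal multiset reading.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coding = universe.coding_ids
    if n > len(coding) and not within_replacement:
        raise ValueError(f"set size {n} exceeds coding universe size {len(coding)}")
    if K < 1:
        raise ValueError("need at least one random set")
    idx = _sample_index_sets(len(coding), n, K, rng, within_replacement)
    arr = np.asarray(coding, dtype=object)
    return [list(arr[row]) for row in idx]


def _sample_index_sets(
    n_genes: int, n: int, K: int, rng: np.random.Generator, within_replacement: bool = False
) -> np.ndarray:
    if within_replacement:
        return rng.integers(0, n_genes, size=(K, n))
    # argsort of uniforms = K independent uniform permutations; take the head
    return np.argsort(rng.random((K, n_genes)), axis=1)[:, :n]


def wilson_interval(x: int, n: int, conf: float = 0.95, continuity: bool = True) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, with continuity correction."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n, n > 0")
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    p = x / n
    if not continuity:
        den = 1 + z * z / n
        center = (p + z * z / (2 * n)) / den
        half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / den
        return max(0.0, center - half), min(1.0, center + half)
    den = 2 * (n + z * z)
    lo = (2 * n * p + z * z - 1 - z * np.sqrt(z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / den
    hi = (2 * n * p + z * z + 1 + z * np.sqrt(z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / den
    if x == 0:
        lo = 0.0
    if x == n:
        hi = 1.0
    return max(0.0, lo), min(1.0, hi)


def one_proportion_chisq(
    x: int,
    n: int,
    p0: float,
    continuity: bool = True,
    category: str = "",
) -> ProportionTestResult:
    """Continuity-corrected one-proportion chi-square test against p0.

    chi2 = n * max(0, |x/n - p0| - 1/(2n))^2 / (p0 (1 - p0)), referred to a
    chi-square distribution with one degree of freedom; the correction is
    clamped at zero so an exact match gives chi2 = 0, p = 1.
    """
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0 < p0 < 1:
        raise ValueError("expected proportion p0 must lie strictly inside (0, 1)")
    d = abs(x / n - p0)
    if continuity:
        d = max(0.0, d - 1 / (2 * n))
    chi2 = n * d * d / (p0 * (1 - p0))
    p = float(stats.chi2.sf(chi2, df=1))
    lo, hi = wilson_interval(x, n, continuity=continuity)
    return ProportionTestResult(
        category=category, x=int(x), n=int(n), p0=float(p0),
        chi2=float(chi2), ci_low=lo, ci_high=hi, p=p,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def category_flag_frame(profiles: Sequence[AnnotationProfile]) -> pd.DataFrame:
    """Boolean gene x category matrix (plus the all-attributes column)."""
    df = pd.DataFrame(
        {
            "brain_expressed": [p.brain_expressed for p in profiles],
            "mouse_trait": [p.mouse_trait for p in profiles],
            "tclin": [p.drug_level == "Tclin" for p in profiles],
            "tchem": [p.drug_level == "Tchem" for p in profiles],
            "tbio": [p.drug_level == "Tbio" for p in profiles],
            "tdark": [p.drug_level == "Tdark" for p in profiles],
            "pgx": [p.pgx for p in profiles],
            "acmg_network": [p.acmg_interaction for p in profiles],
            ALL_ATTRIBUTES: [p.all_categories for p in profiles],
        },
        index=[p.gene for p in profiles],
    )
    return df


def build_null(
    flags: pd.DataFrame,
    sets: Sequence[Sequence[str]],
) -> NullDistribution:
    """Count per-category annotations inside each random gene set.

    ``flags`` is a boolean gene x category matrix covering every sampled
    gene (see :func:`category_flag_frame`).
    """
    sets = list(sets)
    n = len(sets[0])
    flat = pd.Index([g for s in sets for g in s])
    pos = flags.index.get_indexer(flat)
    if (pos < 0).any():
        raise ValueError("random-set gene missing from flag matrix")
    values = flags.to_numpy(dtype=bool)[pos].reshape(len(sets), n, flags.shape[1])
    counts = values.sum(axis=1)
    return NullDistribution(
        counts={c: counts[:, j].astype(int) for j, c in enumerate(flags.columns)},
        n=n,
        K=len(sets),
    )


def category_tests(
    profiles: Sequence[AnnotationProfile],
    null: NullDistribution,
    continuity: bool = True,
    bh_alpha_categories: Sequence[str] = CATEGORIES,
) -> list[ProportionTestResult]:
    """Observed-vs-null one-proportion tests for every reported attribute.

    The eight per-category raw p-values are BH-adjusted together; the
    all-attributes (full intersection) test is appended unadjusted.
    Categories whose null mean is zero are skipped with a warning.
    """
    obs = category_flag_frame(profiles).sum()
    n = len(profiles)
    results: list[ProportionTestResult] = []
    for cat in bh_alpha_categories:
        mean = null.mean(cat)
        if mean <= 0 or mean >= null.n:
            logger.warning("category %s skipped: degenerate null mean %.2f", cat, mean)
            continue
        r = one_proportion_chisq(int(obs[cat]), n, mean / null.n, continuity, category=cat)
        r.expected_mean = mean
        r.expected_sd = null.sd(cat)
        results.append(r)
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    mean_all = null.mean(ALL_ATTRIBUTES)
    if 0 < mean_all < null.n:
        r = one_proportion_chisq(
            int(obs[ALL_ATTRIBUTES]), n, mean_all / null.n, continuity, category=ALL_ATTRIBUTES
        )
        r.expected_mean = mean_all
        r.expected_sd = null.sd(ALL_ATTRIBUTES)
        r.p_adj = None  # reported uncorrected
        results.append(r)
    else:
        logger.warning("all-attributes test skipped: degenerate null mean %.2f", mean_all)
    return results


def category_tests_frame(results: Sequence[ProportionTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "attribute": [r.category for r in results],
            "observed_n": [r.x for r in results],
            "expected_mean": [r.expected_mean for r in results],
            "expected_sd": [r.expected_sd for r in results],
            "chi2": [r.chi2 for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj if r.p_adj is not None else np.nan for r in results],
        }
    )


def _two_group_pillai(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float, int, int, float]:
    """Pillai's trace and its exact-F conversion for a two-group MANOVA.

    With two groups s = 1 and the Pillai F statistic coincides with the
    two-sample Hotelling T-squared F.
    """
    n1, p = x1.shape
    n2 = x2.shape[0]
    N = n1 + n2
    if N - p - 1 <= 0:
        raise ValueError("too few observations for the number of regions")
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    grand = (n1 * m1 + n2 * m2) / N
    H = n1 * np.outer(m1 - grand, m1 - grand) + n2 * np.outer(m2 - grand, m2 - grand)
    E = (x1 - m1).T @ (x1 - m1) + (x2 - m2).T @ (x2 - m2)
    T = H + E
    try:
        sol = np.linalg.solve(T, H)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-group covariance; reduce the number of regions "
            "or add genes"
        ) from exc
    pillai = float(np.trace(sol))
    pillai = min(max(pillai, 0.0), 1.0 - 1e-15)
    df1, df2 = p, N - p - 1
    F = (pillai / (1 - pillai)) * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return pillai, float(F), df1, df2, pval


def expression_contrast(
    expression: pd.DataFrame,
    candidates: Iterable[str],
    random_sets: Sequence[Sequence[str]],
    log_transform: bool = True,
) -> ExpressionContrast:
    """Candidate-vs-random multivariate expression contrast.

    Gene-level region vectors of log2(TPM+1) for the candidate genes are
    compared against the distinct pooled random-set genes (candidates
    excluded from the pool) using Pillai's trace with its standard F
    approximation, followed by per-region univariate F tests with BH
    adjustment.
    """
    cand = [g for g in dict.fromkeys(candidates) if g in expression.index]
    pool_ids = sorted({g for s in random_sets for g in s} - set(cand))
    pool = [g for g in pool_ids if g in expression.index]
    if len(expression.columns) < 2:
        raise ValueError("need at least two regions")
    x1 = expression.loc[cand].to_numpy(dtype=float)
    x2 = expression.loc[pool].to_numpy(dtype=float)
    if log_transform:
        x1 = np.log2(x1 + 1.0)
        x2 = np.log2(x2 + 1.0)
    pillai, F, df1, df2, p = _two_group_pillai(x1, x2)
    regions = list(expression.columns)
    per_f, per_p = [], []
    for j in range(len(regions)):
        fj, pj = stats.f_oneway(x1[:, j], x2[:, j])
        per_f.append(float(fj))
        per_p.append(float(pj))
    per = pd.DataFrame(
        {"region": regions, "F": per_f, "p": per_p, "p_adj": bh_adjust(per_p)}
    )
    return ExpressionContrast(pillai=pillai, F=F, df1=df1, df2=df2, p=p, per_region=per)


def connection_count_test(
    candidate_degrees: Sequence[int],
    random_degrees: Sequence[Sequence[int]],
) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across the candidate set and K random sets."""
    groups = [np.asarray(candidate_degrees)] + [np.asarray(g) for g in random_degrees]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)
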