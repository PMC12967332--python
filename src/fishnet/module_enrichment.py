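"""Module enrichment: rank-based chi-squared scoring of gene sets.

Gene P-values are reduced to their ranks, ranks are mapped to empirical
quantiles p̃ = r/(N+1), and each quantile is transformed to the 1-df
chi-squared value x with P(X ≥ x) = p̃. A module's statistic is the sum of
its members' chi-squared values, tested against a chi-squared distribution
with k degrees of freedom (k = members present in the score universe).
Module P-values are Bonferroni-adjusted for the number of modules actually
tested.

Because the transform depends only on ranks, any strictly monotone
re-expression of the P-values leaves every module P-value unchanged, and the
total chi-squared mass over the universe is a constant determined by N alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .io_formats import GeneScoreTable, ModuleCollection

logger = logging.getLogger("fishnet")

__all__ = [
    "ChiSquareScores",
    "EnrichedModule",
    "rank_transform",
    "score_module",
    "enrich_modules",
    "DEFAULT_MIN_MODULE_SIZE",
]

DEFAULT_MIN_MODULE_SIZE = 3


@dataclass(frozen=True)
class ChiSquareScores:
    """Rank-transformed gene scores.

    ``genes_by_rank[r-1]`` is the gene holding rank r (1 = smallest P; ties
    broken by ascending gene id) and ``chi2_by_rank[r-1]`` the 1-df
    chi-squared value attached to that rank.
    """

    genes_by_rank: tuple[str, ...]
    chi2_by_rank: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.genes_by_rank)

    @property
    def rank(self) -> dict[str, int]:
        return {g: r for r, g in enumerate(self.genes_by_rank, start=1)}

    @property
    def scores(self) -> dict[str, float]:
        return {
            g: float(self.chi2_by_rank[r])
            for r, g in enumerate(self.genes_by_rank)
        }


@dataclass(frozen=True)
class EnrichedModule:
    """One tested module with its sum-of-chi-squared statistic.

    ``k_effective`` counts module genes present in the score universe; the
    test has that many degrees of freedom. ``p_bonferroni`` is
    min(1, p_raw × number of modules tested).
    """

    module_id: str
    k_effective: int
    statistic: float
    p_raw: float
    member_genes: frozenset[str]
    p_bonferroni: float = float("nan")
    significant: bool = False


def rank_transform(table: GeneScoreTable) -> ChiSquareScores:
    """Map gene P-values to 1-df chi-squared values through their ranks.

    Rank r is assigned by ascending P with ties broken by ascending gene id;
    the empirical quantile p̃ = r/(N+1) keeps every quantile strictly inside
    (0, 1). The chi-squared value is the upper-tail quantile at p̃.
    """
    ordered = sorted(table.entries.items(), key=lambda kv: (kv[1], kv[0]))
    genes = tuple(g for g, _ in ordered)
    n = len(genes)
    ptilde = np.arange(1, n + 1, dtype=float) / (n + 1)
    chi2 = stats.chi2.isf(ptilde, df=1)
    return ChiSquareScores(genes_by_rank=genes, chi2_by_rank=chi2)


def score_module(
    chi: ChiSquareScores,
    module_genes: frozenset[str] | set[str],
    module_id: str = "",
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
) -> EnrichedModule | None:
    """Score one module; ``None`` when too few members are in the universe.

    The statistic is the sum of member chi-squared values and the P-value the
    upper tail of a chi-squared distribution with k degrees of freedom. The
    analytic form treats the member values as independent draws; member genes
    absent from the score universe are dropped.
    """
    rank = chi.rank
    members = frozenset(g for g in module_genes if g in rank)
    k = len(members)
    if k < min_module_size:
        logger.info(
            "module %s skipped: %d scored members < min size %d",
            module_id or "<anonymous>", k, min_module_size,
        )
        return None
    idx = np.array(sorted(rank[g] - 1 for g in members), dtype=np.intp)
    statistic = float(chi.chi2_by_rank[idx].sum())
    p_raw = float(stats.chi2.sf(statistic, df=k))
    p_raw = min(max(p_raw, np.nextafter(0.0, 1.0)), 1.0)
    return EnrichedModule(
        module_id=module_id,
        k_effective=k,
        statistic=statistic,
        p_raw=p_raw,
        member_genes=members,
    )


def enrich_modules(
    scores: GeneScoreTable,
    modules: ModuleCollection,
    alpha_module: float = 0.05,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
) -> list[EnrichedModule]:
    """Test every module of sufficient size; Bonferroni-adjust over the tested.

    Returns all tested modules (sorted by ascending raw P, then module id)
    with ``significant`` flagged at p_bonferroni ≤ ``alpha_module``. The
    Bonferroni divisor is the number of modules actually tested after size
    filtering, not the number supplied.
    """
    chi = rank_transform(scores)
    tested: list[EnrichedModule] = []
    for mid in sorted(modules.modules):
        em = score_module(chi, modules.modules[mid], module_id=mid,
                          min_module_size=min_module_size)
        if em is not None:
            tested.append(em)
    if not tested:
        raise ValueError("no module passes the minimum size filter")
    n_tested = len(tested)
    out = [
        replace(
            em,
            p_bonferroni=min(1.0, em.p_raw * n_tested),
            significant=min(1.0, em.p_raw * n_tested) <= alpha_module,
        )
        for em in tested
    ]
    out.sort(key=lambda m: (m.p_raw, m.module_id))
    return out
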