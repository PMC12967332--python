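"""Over-representation analysis of annotation terms within module gene sets.

For each module the overlap of its member genes with every annotation term is
tested with the hypergeometric upper tail, adjusted per module with
Benjamini-Hochberg, and redundant terms (highly overlapping gene sets) are
removed by deterministic greedy Jaccard clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationSet, GeneScoreTable
from .module_enrichment import EnrichedModule

__all__ = [
    "EnrichedTerm",
    "ora_module",
    "ora_universe",
    "bh_adjust",
    "reduce_redundancy",
    "DEFAULT_MIN_OVERLAP",
    "DEFAULT_TERM_FDR",
    "DEFAULT_JACCARD_THRESHOLD",
]

DEFAULT_MIN_OVERLAP = 2
DEFAULT_TERM_FDR = 0.05
DEFAULT_JACCARD_THRESHOLD = 0.5


@dataclass(frozen=True)
class EnrichedTerm:
    """One tested (term, module) pair with its hypergeometric contingency.

    ``p_raw`` = P(X ≥ k_overlap) when drawing ``n_module`` genes from a
    universe of ``n_universe`` containing ``m_term`` term genes; ``q_bh`` is
    BH-adjusted across the terms tested for this module.
    """

    term_id: str
    module_id: str
    overlap_genes: frozenset[str]
    k_overlap: int
    m_term: int
    n_module: int
    n_universe: int
    p_raw: float
    q_bh: float = float("nan")
    enriched: bool = False


def ora_universe(
    scores: GeneScoreTable,
    annotations: AnnotationSet,
    mode: str = "annotated",
) -> set[str]:
    """The reference gene set for over-representation analysis.

    ``annotated`` (default): scored genes appearing in at least one
    annotation term. ``all``: every scored gene.
    """
    if mode == "all":
        return scores.genes()
    if mode == "annotated":
        return scores.genes() & annotations.annotated_genes()
    raise ValueError(f"unknown universe mode {mode!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora_module(
    module: EnrichedModule,
    annotations: AnnotationSet,
    universe: set[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    fdr_threshold: float = DEFAULT_TERM_FDR,
) -> list[EnrichedTerm]:
    """Hypergeometric over-representation of every term in one module.

    Term and module gene sets are intersected with the universe before
    counting. Terms whose overlap with the module is below ``min_overlap``
    are not tested. Returns all tested terms (sorted by ascending raw P,
    then term id) with BH-adjusted values; ``enriched`` flags
    q_bh ≤ ``fdr_threshold``.
    """
    if not universe:
        raise ValueError("empty universe")
    module_in_universe = module.member_genes & universe
    n_module = len(module_in_universe)
    n_universe = len(universe)

    records: list[EnrichedTerm] = []
    for tid in sorted(annotations.terms):
        _, term_genes = annotations.terms[tid]
        term_in_universe = term_genes & universe
        overlap = term_in_universe & module_in_universe
        k = len(overlap)
        if k < min_overlap:
            continue
        m_term = len(term_in_universe)
        # P(X >= k) for X ~ Hypergeom(n_universe, m_term, n_module)
        p_raw = float(stats.hypergeom.sf(k - 1, n_universe, m_term, n_module))
        p_raw = min(max(p_raw, np.nextafter(0.0, 1.0)), 1.0)
        records.append(
            EnrichedTerm(
                term_id=tid,
                module_id=module.module_id,
                overlap_genes=frozenset(overlap),
                k_overlap=k,
                m_term=m_term,
                n_module=n_module,
                n_universe=n_universe,
                p_raw=p_raw,
            )
        )
    if not records:
        return []
    q = bh_adjust([t.p_raw for t in records])
    out = [
        EnrichedTerm(
            term_id=t.term_id,
            module_id=t.module_id,
            overlap_genes=t.overlap_genes,
            k_overlap=t.k_overlap,
            m_term=t.m_term,
            n_module=t.n_module,
            n_universe=t.n_universe,
            p_raw=t.p_raw,
            q_bh=float(qi),
            enriched=bool(qi <= fdr_threshold),
        )
        for t, qi in zip(records, q)
    ]
    out.sort(key=lambda t: (t.p_raw, t.term_id))
    return out


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def reduce_redundancy(
    terms: Iterable[EnrichedTerm],
    jaccard_threshold: float = DEFAULT_JACCARD_THRESHOLD,
) -> list[EnrichedTerm]:
    """Greedy removal of terms with highly overlapping overlap-gene sets.

    Terms (from one module) are scanned by ascending raw P (ties by term id);
    a term is kept iff its Jaccard similarity with every already-kept term's
    overlap genes is below the threshold. A threshold above 1 disables the
    reduction and returns the input unchanged. The most significant term is
    always kept.
    """
    terms = list(terms)
    if jaccard_threshold > 1.0:
        return terms
    kept: list[EnrichedTerm] = []
    for term in sorted(terms, key=lambda t: (t.p_raw, t.term_id)):
        if all(_jaccard(term.overlap_genes, k.overlap_genes) < jaccard_threshold
               for k in kept):
            kept.append(term)
    return kept
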