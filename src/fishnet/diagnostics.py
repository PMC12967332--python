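"""Input-suitability diagnostics and discovery/replication evaluation.

The pipeline assumes that, under the null, P-values fall randomly across the
module structure. That assumption fails when a co-expression network is
built from the same expression data that produced the P-values: genes in a
module then share similar P-values even when those P-values are large. Two
diagnostics expose this:

* **rank reversal** — rerun module enrichment after reversing the ranking
  (most significant genes become least significant). Genes not associated
  with the trait should not cluster in modules, so a clean input yields zero
  significant modules after reversal; a positive count flags dependency
  between the summary statistics and the module structure.
* **module P-value histogram** — a U-shape with excess mass near 1.0 is the
  signature of large-P genes clustering in modules.

Evaluation compares a discovery run against a replication cohort: a hit
(gene, network, algorithm, trait — a *genequad*) is *reproduced* when it is
also a hit in the replication run, and *replicated* when its replication-set
P-value passes the replication set's own Bonferroni threshold 0.05/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneScoreTable, ModuleCollection
from .module_enrichment import (
    DEFAULT_MIN_MODULE_SIZE,
    EnrichedModule,
    enrich_modules,
    rank_transform,
)
from .core import FishnetResult

__all__ = [
    "Genequad",
    "EvalReport",
    "reverse_ranks",
    "rank_reversal_diagnostic",
    "module_p_histogram",
    "evaluate",
]


@dataclass(frozen=True)
class Genequad:
    """Unique identifier of one hit: gene × network × algorithm × trait."""

    gene_id: str
    network_label: str
    algorithm_label: str
    trait_label: str

    def __post_init__(self) -> None:
        for f in (self.gene_id, self.network_label,
                  self.algorithm_label, self.trait_label):
            if not f:
                raise ValueError("genequad fields must be non-empty")


@dataclass(frozen=True)
class EvalReport:
    """Reproduction and replication counts for one discovery/replication pair."""

    n_quads: int
    n_replicated: int
    replication_rate: float | None
    bonferroni_alpha_replication: float
    n_reproduced: int | None = None
    reproduction_rate: float | None = None
    replicated_genes: tuple[str, ...] = ()
    reproduced_genes: tuple[str, ...] = ()
    missing_from_replication: tuple[str, ...] = ()


def reverse_ranks(scores: GeneScoreTable) -> GeneScoreTable:
    """Give the gene at rank r the P-value originally held by rank N+1−r.

    The multiset of P-values is preserved exactly; applying the operation
    twice restores the original gene → P assignment (up to tie ordering).
    """
    chi = rank_transform(scores)
    genes = chi.genes_by_rank
    values = [scores[g] for g in genes]
    return GeneScoreTable(
        entries={g: values[len(genes) - 1 - r] for r, g in enumerate(genes)}
    )


def rank_reversal_diagnostic(
    scores: GeneScoreTable,
    modules: ModuleCollection,
    alpha_module: float = 0.05,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
) -> int:
    """Number of Bonferroni-significant modules after rank reversal.

    0 indicates the inputs are suitable; a positive count flags dependency
    between the summary statistics and the module structure.
    """
    try:
        enriched = enrich_modules(
            reverse_ranks(scores), modules,
            alpha_module=alpha_module, min_module_size=min_module_size,
        )
    except ValueError:
        return 0
    return sum(m.significant for m in enriched)


def module_p_histogram(
    modules_tested: list[EnrichedModule], n_bins: int = 20
) -> pd.DataFrame:
    """Equal-width histogram of raw module P-values on [0, 1]."""
    if not modules_tested:
        raise ValueError("no tested modules supplied")
    p = np.array([m.p_raw for m in modules_tested])
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def evaluate(
    discovery: FishnetResult,
    replication_scores: GeneScoreTable,
    replication_result: FishnetResult | None = None,
    network_label: str = "network",
    algorithm_label: str = "algorithm",
    trait_label: str = "trait",
) -> EvalReport:
    """Score a discovery run against a replication cohort.

    A discovery gene is *replicated* when its replication-set P-value is at
    most 0.05 / N_replication (the replication set's own Bonferroni
    threshold); genes absent from the replication universe count as not
    replicated and are listed. It is *reproduced* when it is also a hit in
    ``replication_result`` (labels are assumed identical between the runs);
    reproduction fields are omitted when no replication result is supplied.
    """
    quads = sorted(
        Genequad(g, network_label, algorithm_label, trait_label).gene_id
        for g in discovery.genes
    )
    n_quads = len(quads)
    alpha = 0.05 / replication_scores.n_genes

    replicated, missing = [], []
    for g in quads:
        if g not in replication_scores:
            missing.append(g)
        elif replication_scores[g] <= alpha:
            replicated.append(g)

    n_reproduced = None
    reproduction_rate = None
    reproduced: list[str] = []
    if replication_result is not None:
        reproduced = [g for g in quads if g in replication_result.genes]
        n_reproduced = len(reproduced)
        reproduction_rate = n_reproduced / n_quads if n_quads else None

    return EvalReport(
        n_quads=n_quads,
        n_replicated=len(replicated),
        replication_rate=len(replicated) / n_quads if n_quads else None,
        bonferroni_alpha_replication=alpha,
        n_reproduced=n_reproduced,
        reproduction_rate=reproduction_rate,
        replicated_genes=tuple(replicated),
        reproduced_genes=tuple(reproduced),
        missing_from_replication=tuple(missing),
    )
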