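"""Candidate gene sets, rank permutations, and the empirical FDR/quantile search.

A gene is a candidate when it (1) lies in a module significantly enriched for
low P-values and (2) is annotated by a functional term enriched in that
module (after redundancy reduction). Let A_0 be the candidate set under the
true ranks and A_1..A_M the candidate sets under M uniform permutations of
the gene → rank assignment. With B_j the top-j genes by the observed
P-values and C_ij = A_i ∩ B_j:

    FDR_j      = mean(|C_1j|, ..., |C_Mj|) / |C_0j|
    quantile_j = fraction of |C_ij| (i ≥ 1) strictly below |C_0j|

The rank-filter search walks j downward from 5% of genes in steps of 10 and
returns A_0 ∩ B_j at the first j meeting FDR ≤ 0.05 and quantile ≥ 0.99 (all
four numbers configurable). The module-filter search instead tightens the
Bonferroni-adjusted module P-value threshold from 0.1 downward, rebuilding
the candidate sets at each threshold.

Because the enrichment statistic is purely rank-based, permuting the
gene → rank map is equivalent to permuting the raw P-values among genes.
And because a module's over-representation result depends only on its member
set — never on P-values — ORA is computed once per module and cached across
all permutations, with results identical to recomputing it for every run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import AnnotationSet, GeneScoreTable, ModuleCollection
from .module_enrichment import (
    DEFAULT_MIN_MODULE_SIZE,
    EnrichedModule,
    rank_transform,
)
from .function_enrichment import (
    DEFAULT_JACCARD_THRESHOLD,
    DEFAULT_MIN_OVERLAP,
    DEFAULT_TERM_FDR,
    EnrichedTerm,
    ora_module,
    ora_universe,
    reduce_redundancy,
)

logger = logging.getLogger("fishnet")

__all__ = [
    "EnrichmentParams",
    "PermutationConfig",
    "GeneProvenance",
    "CandidateEnsemble",
    "FishnetResult",
    "candidate_genes",
    "permute_and_collect",
    "top_genes",
    "compute_fdr",
    "compute_quantile",
    "rank_filter_search",
    "module_filter_search",
    "simple_mode",
    "default_module_filter_schedule",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentParams:
    """Parameters of the two enrichment stages feeding candidate selection."""

    alpha_module: float = 0.05
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE
    min_overlap: int = DEFAULT_MIN_OVERLAP
    term_fdr: float = DEFAULT_TERM_FDR
    jaccard_threshold: float = DEFAULT_JACCARD_THRESHOLD
    universe_mode: str = "annotated"


def default_module_filter_schedule(
    start: float = 0.1, stop: float = 1e-6
) -> tuple[float, ...]:
    """Geometric halving schedule of module-P thresholds, start down to stop."""
    out = []
    t = start
    while t >= stop:
        out.append(t)
        t /= 2.0
    return tuple(out)


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the permutation-based empirical hypothesis test.

    Defaults: M = 200 permutations, FDR ≤ 0.05, quantile ≥ 0.99, j starting
    at 5% of genes and decreasing in steps of 10 down to 10. Thresholds
    outside FDR 0.01–0.10 or quantile 0.80–0.99 trigger a warning (behaviour
    outside those ranges is untested territory).
    """

    M: int = 200
    fdr_threshold: float = 0.05
    quantile_threshold: float = 0.99
    j_init_fraction: float = 0.05
    j_step: int = 10
    j_min: int = 10
    seed: int = 0
    mode: str = "rank_filter"
    module_filter_schedule: tuple[float, ...] = field(
        default_factory=default_module_filter_schedule
    )

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.j_step < 1 or self.j_min < 1:
            raise ValueError("j_step and j_min must be >= 1")
        if not (0.0 < self.j_init_fraction <= 1.0):
            raise ValueError("j_init_fraction must lie in (0, 1]")
        if self.mode not in ("simple", "rank_filter", "module_filter"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.01 <= self.fdr_threshold <= 0.10):
            warnings.warn(
                f"fdr_threshold {self.fdr_threshold} is outside the "
                "tested range [0.01, 0.10]",
                stacklevel=2,
            )
        if not (0.80 <= self.quantile_threshold <= 0.99):
            warnings.warn(
                f"quantile_threshold {self.quantile_threshold} is outside "
                "the tested range [0.80, 0.99]",
                stacklevel=2,
            )


@dataclass(frozen=True)
class GeneProvenance:
    """Why one gene is a candidate: its P, rank, modules, and terms."""

    p: float
    rank: int
    module_ids: tuple[str, ...]
    term_ids: tuple[str, ...]


@dataclass
class CandidateEnsemble:
    """Observed candidate set A_0 plus M permuted candidate sets A_1..A_M."""

    observed: frozenset[str]
    permuted: list[frozenset[str]]
    perm_sig_module_counts: list[int]
    genes_by_rank: tuple[str, ...] = ()
    provenance: dict[str, GeneProvenance] = field(default_factory=dict)
    observed_modules: list[EnrichedModule] = field(default_factory=list)
    observed_terms: list[EnrichedTerm] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.permuted)


@dataclass
class FishnetResult:
    """Final gene set with the search trace and per-gene provenance."""

    genes: frozenset[str]
    mode: str
    accepted: bool | None
    j_final: int | None = None
    module_p_threshold_final: float | None = None
    c0: int | None = None
    fdr: float | None = None
    quantile: float | None = None
    n_candidates: int = 0
    provenance: dict[str, GeneProvenance] = field(default_factory=dict)
    trace: list[dict] = field(default_factory=list)
    config: PermutationConfig | None = None
    params: EnrichmentParams | None = None

    def config_echo(self) -> dict:
        out: dict = {"mode": self.mode}
        if self.config is not None:
            out.update(
                M=self.config.M,
                fdr_threshold=self.config.fdr_threshold,
                quantile_threshold=self.config.quantile_threshold,
                j_init_fraction=self.config.j_init_fraction,
                j_step=self.config.j_step,
                j_min=self.config.j_min,
                seed=self.config.seed,
            )
        if self.params is not None:
            out.update(
                alpha_module=self.params.alpha_module,
                min_module_size=self.params.min_module_size,
                min_overlap=self.params.min_overlap,
                term_fdr=self.params.term_fdr,
                jaccard_threshold=self.params.jaccard_threshold,
                universe_mode=self.params.universe_mode,
                tie_break="ascending gene id",
            )
        return out


# ---------------------------------------------------------------------------
# Engine: vectorized module scoring + per-module ORA cache
# ---------------------------------------------------------------------------

class _Engine:
    """Shared machinery for the observed run and all permutations.

    Holds rank-indexed chi-squared values, module member index arrays, and a
    lazy per-module cache of (kept enriched terms, candidate genes). Module
    statistics under a permutation are sums of chi-squared values at permuted
    positions; summation runs over values sorted descending so that the
    result is bit-identical to the public :func:`score_module` path.
    """

    def __init__(
        self,
        scores: GeneScoreTable,
        modules: ModuleCollection,
        annotations: AnnotationSet,
        params: EnrichmentParams,
    ) -> None:
        self.scores = scores
        self.modules = modules
        self.annotations = annotations
        self.params = params
        self.chi = rank_transform(scores)
        self.n = self.chi.n_genes
        rank = self.chi.rank
        self.module_ids: list[str] = []
        self.member_idx: list[np.ndarray] = []
        self.member_sets: list[frozenset[str]] = []
        for mid in sorted(modules.modules):
            members = frozenset(
                g for g in modules.modules[mid] if g in rank
            )
            if len(members) < params.min_module_size:
                continue
            self.module_ids.append(mid)
            self.member_sets.append(members)
            self.member_idx.append(
                np.array(sorted(rank[g] - 1 for g in members), dtype=np.intp)
            )
        self.k_arr = np.array([len(s) for s in self.member_sets], dtype=float)
        self.n_tested = len(self.module_ids)
        self.universe = ora_universe(scores, annotations, params.universe_mode)
        self._ora_cache: dict[str, tuple[list[EnrichedTerm], frozenset[str]]] = {}

    # -- module P-values ----------------------------------------------------

    def module_p(self, perm: np.ndarray | None = None) -> np.ndarray:
        """Raw module P-values under one rank assignment (None = observed)."""
        if self.n_tested == 0:
            return np.empty(0)
        chi2 = self.chi.chi2_by_rank
        statistic = np.empty(self.n_tested)
        for m, idx in enumerate(self.member_idx):
            vals = chi2[idx] if perm is None else chi2[perm[idx]]
            # summed in descending order, matching score_module bit-for-bit
            statistic[m] = np.sort(vals)[::-1].sum()
        p = stats.chi2.sf(statistic, df=self.k_arr)
        tiny = np.nextafter(0.0, 1.0)
        return np.clip(p, tiny, 1.0)

    def significant_mask(self, p_raw: np.ndarray) -> np.ndarray:
        return np.minimum(1.0, p_raw * self.n_tested) <= self.params.alpha_module

    def enriched_modules(self, p_raw: np.ndarray) -> list[EnrichedModule]:
        """EnrichedModule records for the observed run (report output)."""
        sig = self.significant_mask(p_raw)
        chi2 = self.chi.chi2_by_rank
        out = []
        for m, mid in enumerate(self.module_ids):
            out.append(
                EnrichedModule(
                    module_id=mid,
                    k_effective=int(self.k_arr[m]),
                    statistic=float(chi2[self.member_idx[m]].sum()),
                    p_raw=float(p_raw[m]),
                    member_genes=self.member_sets[m],
                    p_bonferroni=float(min(1.0, p_raw[m] * self.n_tested)),
                    significant=bool(sig[m]),
                )
            )
        out.sort(key=lambda m: (m.p_raw, m.module_id))
        return out

    # -- per-module ORA (rank-independent, hence cacheable) -----------------

    def module_ora(self, m: int) -> tuple[list[EnrichedTerm], frozenset[str]]:
        mid = self.module_ids[m]
        if mid not in self._ora_cache:
            shell = EnrichedModule(
                module_id=mid,
                k_effective=int(self.k_arr[m]),
                statistic=float("nan"),
                p_raw=1.0,
                member_genes=self.member_sets[m],
            )
            tested = ora_module(
                shell,
                self.annotations,
                self.universe,
                min_overlap=self.params.min_overlap,
                fdr_threshold=self.params.term_fdr,
            )
            kept = reduce_redundancy(
                [t for t in tested if t.enriched],
                jaccard_threshold=self.params.jaccard_threshold,
            )
            overlap_union: set[str] = set()
            for t in kept:
                overlap_union |= t.overlap_genes
            cand = frozenset(self.member_sets[m] & overlap_union)
            self._ora_cache[mid] = (kept, cand)
        return self._ora_cache[mid]

    def candidate_set(self, sig_indices: np.ndarray) -> frozenset[str]:
        out: set[str] = set()
        for m in sig_indices:
            out |= self.module_ora(int(m))[1]
        return frozenset(out)

    def provenance_for(
        self, genes: frozenset[str], sig_indices: np.ndarray
    ) -> dict[str, GeneProvenance]:
        rank = self.chi.rank
        mods: dict[str, list[str]] = {g: [] for g in genes}
        trms: dict[str, list[str]] = {g: [] for g in genes}
        for m in sig_indices:
            kept, cand = self.module_ora(int(m))
            for g in cand & genes:
                mods[g].append(self.module_ids[int(m)])
                for t in kept:
                    if g in t.overlap_genes and t.term_id not in trms[g]:
                        trms[g].append(t.term_id)
        return {
            g: GeneProvenance(
                p=self.scores[g],
                rank=rank[g],
                module_ids=tuple(sorted(mods[g])),
                term_ids=tuple(sorted(trms[g])),
            )
            for g in genes
        }


def _perm_rng(seed: int, i: int) -> np.random.Generator:
    # child seed for permutation i: independent of execution order
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(i,))
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def _j_init(n: int, config: PermutationConfig) -> int:
    return min(n, max(config.j_min, _round_half_away(config.j_init_fraction * n)))


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def candidate_genes(
    scores: GeneScoreTable,
    modules: ModuleCollection,
    annotations: AnnotationSet,
    params: EnrichmentParams | None = None,
) -> frozenset[str]:
    """Genes in a significant module AND in a kept enriched term of it (A_0)."""
    params = params or EnrichmentParams()
    engine = _Engine(scores, modules, annotations, params)
    if engine.n_tested == 0:
        return frozenset()
    p_raw = engine.module_p()
    sig = np.flatnonzero(engine.significant_mask(p_raw))
    return engine.candidate_set(sig)


def permute_and_collect(
    scores: GeneScoreTable,
    modules: ModuleCollection,
    annotations: AnnotationSet,
    config: PermutationConfig,
    params: EnrichmentParams | None = None,
) -> CandidateEnsemble:
    """Build A_0 and the M permuted candidate sets A_1..A_M.

    Permutation i reassigns the observed rank multiset to genes uniformly at
    random, using a child seed derived from (config.seed, i), then reruns
    module enrichment and candidate selection. Deterministic given the seed.
    """
    params = params or EnrichmentParams()
    engine = _Engine(scores, modules, annotations, params)

    if engine.n_tested == 0:
        return CandidateEnsemble(
            observed=frozenset(),
            permuted=[frozenset()] * config.M,
            perm_sig_module_counts=[0] * config.M,
            genes_by_rank=engine.chi.genes_by_rank,
        )

    p0 = engine.module_p()
    sig0 = np.flatnonzero(engine.significant_mask(p0))
    observed = engine.candidate_set(sig0)
    provenance = engine.provenance_for(observed, sig0)
    observed_modules = engine.enriched_modules(p0)
    observed_terms: list[EnrichedTerm] = []
    for m in sig0:
        observed_terms.extend(engine.module_ora(int(m))[0])

    permuted: list[frozenset[str]] = []
    counts: list[int] = []
    for i in range(1, config.M + 1):
        perm = _perm_rng(config.seed, i).permutation(engine.n)
        p_i = engine.module_p(perm)
        sig_i = np.flatnonzero(engine.significant_mask(p_i))
        counts.append(int(sig_i.size))
        permuted.append(engine.candidate_set(sig_i))

    return CandidateEnsemble(
        observed=observed,
        permuted=permuted,
        perm_sig_module_counts=counts,
        genes_by_rank=engine.chi.genes_by_rank,
        provenance=provenance,
        observed_modules=observed_modules,
        observed_terms=observed_terms,
    )


def top_genes(scores: GeneScoreTable, j: int) -> frozenset[str]:
    """B_j: the j genes with the smallest P-values (observed ranks only)."""
    n = scores.n_genes
    if not (1 <= j <= n):
        raise ValueError(f"j must lie in [1, {n}], got {j}")
    chi = rank_transform(scores)
    return frozenset(chi.genes_by_rank[:j])


def compute_fdr(c0: int, perm_counts: list[int]) -> float | None:
    """Empirical FDR = mean permutation count / c0; None when c0 = 0."""
    if c0 < 0:
        raise ValueError("c0 must be non-negative")
    if c0 == 0:
        return None
    return float(np.mean(perm_counts)) / c0


def compute_quantile(c0: int, perm_counts: list[int]) -> float:
    """Fraction of permutation counts strictly below c0 (ties do not count)."""
    counts = np.asarray(perm_counts)
    return float(np.count_nonzero(counts < c0) / counts.size)


def _passes(fdr: float | None, quantile: float,
            config: PermutationConfig) -> bool:
    return (
        fdr is not None
        and fdr <= config.fdr_threshold
        and quantile >= config.quantile_threshold
    )


def rank_filter_search(
    ensemble: CandidateEnsemble,
    scores: GeneScoreTable,
    config: PermutationConfig,
    params: EnrichmentParams | None = None,
) -> FishnetResult:
    """Walk j downward until A_0 ∩ B_j meets the FDR and quantile criteria.

    B_j is always taken from the observed P-values, including when
    intersecting with permuted candidate sets.
    """
    n = scores.n_genes
    genes_by_rank = ensemble.genes_by_rank or rank_transform(scores).genes_by_rank
    pos = {g: i for i, g in enumerate(genes_by_rank)}

    base = dict(
        mode="rank_filter",
        n_candidates=len(ensemble.observed),
        config=config,
        params=params,
    )
    if not ensemble.observed:
        return FishnetResult(genes=frozenset(), accepted=False, **base)

    pos0 = np.sort([pos[g] for g in ensemble.observed])
    pos_perm = [np.sort([pos[g] for g in a]) for a in ensemble.permuted]

    trace: list[dict] = []
    j = _j_init(n, config)
    while j >= config.j_min:
        c0 = int(np.searchsorted(pos0, j))
        counts = [int(np.searchsorted(p, j)) for p in pos_perm]
        fdr = compute_fdr(c0, counts)
        quantile = compute_quantile(c0, counts)
        trace.append(
            dict(j=j, c0=c0, mean_perm_count=float(np.mean(counts)),
                 fdr=fdr, quantile=quantile)
        )
        if _passes(fdr, quantile, config):
            genes = frozenset(g for g in ensemble.observed if pos[g] < j)
            return FishnetResult(
                genes=genes,
                accepted=True,
                j_final=j,
                c0=c0,
                fdr=fdr,
                quantile=quantile,
                provenance={g: ensemble.provenance[g] for g in genes
                            if g in ensemble.provenance},
                trace=trace,
                **base,
            )
        j -= config.j_step
    return FishnetResult(genes=frozenset(), accepted=False, trace=trace, **base)


def module_filter_search(
    scores: GeneScoreTable,
    modules: ModuleCollection,
    annotations: AnnotationSet,
    config: PermutationConfig,
    params: EnrichmentParams | None = None,
) -> FishnetResult:
    """Tighten the module-P threshold until the FDR/quantile criteria are met.

    At threshold t the candidate set A_i(t) is built from modules with
    Bonferroni-adjusted P ≤ t in run i (observed or permuted); the top-j
    gene filter is not applied in this mode. The default schedule halves t
    from 0.1 down to 1e-6.
    """
    params = params or EnrichmentParams()
    engine = _Engine(scores, modules, annotations, params)
    base = dict(mode="module_filter", config=config, params=params)
    if engine.n_tested == 0:
        return FishnetResult(genes=frozenset(), accepted=False,
                             n_candidates=0, **base)

    pb0 = np.minimum(1.0, engine.module_p() * engine.n_tested)
    pb_perm = np.empty((config.M, engine.n_tested))
    for i in range(1, config.M + 1):
        perm = _perm_rng(config.seed, i).permutation(engine.n)
        pb_perm[i - 1] = np.minimum(1.0, engine.module_p(perm) * engine.n_tested)

    trace: list[dict] = []
    schedule = config.module_filter_schedule or default_module_filter_schedule()
    n_cand_initial = len(engine.candidate_set(np.flatnonzero(pb0 <= schedule[0])))
    for t in schedule:
        sig0 = np.flatnonzero(pb0 <= t)
        a0 = engine.candidate_set(sig0)
        c0 = len(a0)
        counts = [
            len(engine.candidate_set(np.flatnonzero(pb_perm[i] <= t)))
            for i in range(config.M)
        ]
        fdr = compute_fdr(c0, counts)
        quantile = compute_quantile(c0, counts)
        trace.append(
            dict(module_p_threshold=t, c0=c0,
                 mean_perm_count=float(np.mean(counts)),
                 fdr=fdr, quantile=quantile)
        )
        if _passes(fdr, quantile, config):
            return FishnetResult(
                genes=a0,
                accepted=True,
                module_p_threshold_final=t,
                c0=c0,
                fdr=fdr,
                quantile=quantile,
                n_candidates=n_cand_initial,
                provenance=engine.provenance_for(a0, sig0),
                trace=trace,
                **base,
            )
    return FishnetResult(genes=frozenset(), accepted=False,
                         n_candidates=n_cand_initial, trace=trace, **base)


def simple_mode(
    scores: GeneScoreTable,
    modules: ModuleCollection,
    annotations: AnnotationSet,
    config: PermutationConfig | None = None,
    params: EnrichmentParams | None = None,
) -> FishnetResult:
    """A_0 intersected once with the top-5% gene filter; no permutations."""
    config = config or PermutationConfig(mode="simple")
    params = params or EnrichmentParams()
    engine = _Engine(scores, modules, annotations, params)
    if engine.n_tested == 0:
        return FishnetResult(genes=frozenset(), mode="simple", accepted=None,
                             config=config, params=params)
    p0 = engine.module_p()
    sig0 = np.flatnonzero(engine.significant_mask(p0))
    a0 = engine.candidate_set(sig0)
    j = _j_init(engine.n, config)
    b = frozenset(engine.chi.genes_by_rank[:j])
    genes = a0 & b
    return FishnetResult(
        genes=genes,
        mode="simple",
        accepted=None,
        j_final=j,
        n_candidates=len(a0),
        provenance=engine.provenance_for(genes, sig0),
        config=config,
        params=params,
    )
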