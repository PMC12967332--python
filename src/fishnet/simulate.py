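"""Seeded synthetic inputs: gene universes, modules, annotations, P-values.

The generator emulates the statistical structure the method assumes: genes
whose P-values are low by chance fall randomly across modules and functions.
Background genes draw p ~ Uniform(0,1); planted modules draw from a spike
model (Beta(a,1) with a < 1 for low-P enrichment, or its mirror 1−Beta(a,1)
for a cluster of large P-values), and each planted module is paired with an
annotation term covering a configurable fraction of its genes.

A second generator produces the pathological case of module-correlated
P-values (each module's genes share a module-level center), which yields the
U-shaped module P-value distribution that the rank-reversal diagnostic is
designed to flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AnnotationSet, GeneScoreTable, ModuleCollection
from .core import FishnetResult

__all__ = [
    "SignalModel",
    "FixtureSpec",
    "generate",
    "generate_dependent_pair",
    "recovery_score",
]

_TINY = 1e-300


@dataclass(frozen=True)
class SignalModel:
    """Generative model for the P-values of one planted module.

    kinds: ``beta`` — p ~ Beta(a, b) (a < 1, b = 1 gives the usual low-P
    spike); ``uniform`` — no signal; ``large_p`` — p ~ 1 − Beta(a, b), a
    cluster of P-values near 1.
    """

    kind: str = "beta"
    a: float = 0.1
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "uniform", "large_p"):
            raise ValueError(f"unknown signal model {self.kind!r}")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "uniform":
            p = rng.uniform(0.0, 1.0, size)
        elif self.kind == "beta":
            p = rng.beta(self.a, self.b, size)
        else:
            p = 1.0 - rng.beta(self.a, self.b, size)
        return np.clip(p, _TINY, 1.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one synthetic input triple.

    Defaults (1000 genes, 50 modules of 10–30 genes, 100 annotation terms)
    are sized so that a full permutation search with M = 200 completes in
    seconds. ``planted_modules`` pairs a module index with a signal model;
    ``annotation_alignment`` is the fraction of a planted module covered by
    its planted term.
    """

    n_genes: int = 1000
    n_modules: int = 50
    module_size_range: tuple[int, int] = (10, 30)
    n_terms: int = 100
    term_size_range: tuple[int, int] = (10, 50)
    planted_modules: tuple[tuple[int, SignalModel], ...] = ()
    annotation_alignment: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.module_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid module size range")
        if self.n_modules * lo > self.n_genes:
            raise ValueError(
                f"{self.n_modules} modules of >= {lo} genes exceed a "
                f"{self.n_genes}-gene universe"
            )
        if not (0.0 <= self.annotation_alignment <= 1.0):
            raise ValueError("annotation_alignment must lie in [0, 1]")
        for idx, model in self.planted_modules:
            if not (0 <= idx < self.n_modules):
                raise ValueError(f"planted module index {idx} out of range")
            if not isinstance(model, SignalModel):
                raise ValueError("planted signal must be a SignalModel")


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _module_sizes(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.module_size_range
    sizes = rng.integers(lo, hi + 1, spec.n_modules)
    # repair draws that overflow the universe: shrink the largest modules,
    # never below the minimum, so the partition always fits
    while sizes.sum() > spec.n_genes:
        sizes[int(np.argmax(sizes))] -= 1
    return sizes


def _partition_modules(
    spec: FixtureSpec, rng: np.random.Generator, genes: list[str]
) -> dict[str, frozenset[str]]:
    sizes = _module_sizes(spec, rng)
    order = rng.permutation(spec.n_genes)
    modules: dict[str, frozenset[str]] = {}
    start = 0
    width = len(str(spec.n_modules))
    for m, size in enumerate(sizes, start=1):
        chunk = order[start:start + size]
        modules[f"m{m:0{width}d}"] = frozenset(genes[i] for i in chunk)
        start += size
    return modules


def _decoy_terms(
    spec: FixtureSpec, rng: np.random.Generator, genes: list[str]
) -> dict[str, tuple[str, frozenset[str]]]:
    lo, hi = spec.term_size_range
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    width = len(str(max(spec.n_terms, 1)))
    for t in range(1, spec.n_terms + 1):
        size = int(rng.integers(lo, min(hi, spec.n_genes) + 1))
        members = rng.choice(spec.n_genes, size=size, replace=False)
        terms[f"T{t:0{width}d}"] = (
            f"decoy process {t}",
            frozenset(genes[i] for i in members),
        )
    return terms


def generate(
    spec: FixtureSpec,
) -> tuple[GeneScoreTable, ModuleCollection, AnnotationSet, dict[str, frozenset[str]]]:
    """Generate (scores, modules, annotations, truth) for one fixture.

    Modules partition a random subset of the universe disjointly. Each
    planted module receives P-values from its signal model and one aligned
    annotation term (covering ``annotation_alignment`` of its genes plus a
    few random decoy genes). ``truth`` maps each planted module id to its
    gene set; it is empty for null fixtures. Bit-identical per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    genes = _gene_names(spec.n_genes)
    modules = _partition_modules(spec, rng, genes)
    module_ids = sorted(modules)

    p = np.clip(rng.uniform(0.0, 1.0, spec.n_genes), _TINY, 1.0)
    index = {g: i for i, g in enumerate(genes)}
    truth: dict[str, frozenset[str]] = {}
    for idx, model in spec.planted_modules:
        mid = module_ids[idx]
        members = sorted(modules[mid])
        p[[index[g] for g in members]] = model.draw(rng, len(members))
        truth[mid] = modules[mid]

    terms = _decoy_terms(spec, rng, genes)
    for mid in sorted(truth):
        members = sorted(truth[mid])
        n_cover = int(round(spec.annotation_alignment * len(members)))
        covered = rng.choice(len(members), size=n_cover, replace=False)
        outside = sorted(set(genes) - truth[mid])
        extras = rng.choice(len(outside), size=min(5, len(outside)),
                            replace=False)
        term_genes = frozenset(
            [members[i] for i in covered] + [outside[i] for i in extras]
        )
        if term_genes:
            terms[f"T_planted_{mid}"] = (f"planted process {mid}", term_genes)

    scores = GeneScoreTable(entries={g: float(p[i]) for i, g in enumerate(genes)})
    return (
        scores,
        ModuleCollection(modules=modules, source_label="synthetic",
                         algorithm_label="partition"),
        AnnotationSet(terms=terms),
        truth,
    )


def generate_dependent_pair(
    spec: FixtureSpec, concentration: float = 50.0
) -> tuple[GeneScoreTable, ModuleCollection, AnnotationSet]:
    """A fixture with module-correlated P-values (the unsuitable-input case).

    Each module draws a center c ~ Uniform(0,1); its genes draw
    p ~ Beta(1 + κc, 1 + κ(1−c)), so modules share low or high P-value
    centers. κ = ``concentration``; κ = 0 reduces to the independent uniform
    fixture. Genes outside any module stay Uniform(0,1).
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    genes = _gene_names(spec.n_genes)
    modules = _partition_modules(spec, rng, genes)

    p = np.clip(rng.uniform(0.0, 1.0, spec.n_genes), _TINY, 1.0)
    index = {g: i for i, g in enumerate(genes)}
    for mid in sorted(modules):
        c = rng.uniform(0.0, 1.0)
        members = sorted(modules[mid])
        draws = rng.beta(1.0 + concentration * c,
                         1.0 + concentration * (1.0 - c), len(members))
        p[[index[g] for g in members]] = np.clip(draws, _TINY, 1.0)

    terms = _decoy_terms(spec, rng, genes)
    scores = GeneScoreTable(entries={g: float(p[i]) for i, g in enumerate(genes)})
    return (
        scores,
        ModuleCollection(modules=modules, source_label="synthetic-dependent",
                         algorithm_label="partition"),
        AnnotationSet(terms=terms),
    )


def recovery_score(
    result: FishnetResult, truth: frozenset[str] | set[str]
) -> tuple[float, float]:
    """(precision, recall) of a result against the planted gene set.

    Precision is 1.0 by convention when the result is empty (no false
    positives were made); recall requires a non-empty truth set.
    """
    truth = frozenset(truth)
    if not truth:
        raise ValueError("truth set is empty")
    hit = len(result.genes & truth)
    precision = hit / len(result.genes) if result.genes else 1.0
    recall = hit / len(truth)
    return precision, recall
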