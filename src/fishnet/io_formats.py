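"""Input/output of the three external data types and of result reports.

The pipeline consumes only flat gene sets and a gene → P-value map:

* gene-level summary statistics — delimited text with a header row;
* network modules — either the MONET line-per-module dialect (module id,
  optional numeric score, then gene ids, tab-separated) or GMT;
* functional annotation terms — GMT (term id, description, gene ids).

Gene identifiers are matched by exact string comparison after trimming
surrounding whitespace; no symbol/alias resolution is attempted and case is
preserved (identifier spaces such as Ensembl are case-stable, and folding
could merge distinct ids).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .module_enrichment import EnrichedModule
    from .function_enrichment import EnrichedTerm
    from .core import FishnetResult

logger = logging.getLogger("fishnet")

__all__ = [
    "GeneScoreTable",
    "ModuleCollection",
    "AnnotationSet",
    "read_gene_scores",
    "read_modules",
    "read_gmt",
    "write_modules",
    "write_gmt",
    "write_report",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneScoreTable:
    """A validated gene → P-value map; the analysis universe.

    Every P-value must lie in (0, 1]; gene ids must be unique non-empty
    strings. The number of genes N defines the rank scale used throughout.
    """

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("gene score table is empty")
        for gene, p in self.entries.items():
            if not isinstance(gene, str) or not gene.strip():
                raise ValueError(f"invalid gene id: {gene!r}")
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p-value out of range (0, 1] for {gene!r}: {p}")

    @property
    def n_genes(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __getitem__(self, gene: str) -> float:
        return self.entries[gene]

    def genes(self) -> set[str]:
        return set(self.entries)


@dataclass(frozen=True)
class ModuleCollection:
    """Named gene sets from one (network, module-detection algorithm) pair.

    Only the set of genes in each module is stored; internal connectivity is
    never used downstream.
    """

    modules: Mapping[str, frozenset[str]]
    source_label: str = ""
    algorithm_label: str = ""

    def __post_init__(self) -> None:
        for mid, genes in self.modules.items():
            if not mid or not isinstance(mid, str):
                raise ValueError(f"invalid module id: {mid!r}")
            if not genes:
                raise ValueError(f"module {mid!r} is empty")

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules.items())


@dataclass(frozen=True)
class AnnotationSet:
    """Functional annotation terms: term id → (name, gene set)."""

    terms: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not tid or not isinstance(tid, str):
                raise ValueError(f"invalid term id: {tid!r}")
            if not genes:
                raise ValueError(f"annotation term {tid!r} has no genes")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def annotated_genes(self) -> set[str]:
        """Union of all term gene sets."""
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_gene_scores(
    path: str | Path, gene_column: str = "gene", p_column: str = "p"
) -> GeneScoreTable:
    """Read a delimited gene score table (TSV by default, CSV by suffix).

    Rows with missing or non-numeric P-values are dropped with a warning;
    duplicate gene ids and out-of-range P-values are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for col in (gene_column, p_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    entries: dict[str, float] = {}
    for row_no, (gene, p_str) in enumerate(
        zip(df[gene_column], df[p_column]), start=2
    ):
        gene = str(gene).strip() if pd.notna(gene) else ""
        try:
            p = float(p_str)
        except (TypeError, ValueError):
            logger.warning("row %d of %s: non-numeric p-value %r; skipped",
                           row_no, path, p_str)
            continue
        if pd.isna(p):
            logger.warning("row %d of %s: missing p-value; skipped", row_no, path)
            continue
        if not gene:
            raise ValueError(f"row {row_no} of {path}: empty gene id")
        if gene in entries:
            raise ValueError(f"duplicate gene id {gene!r} in {path}")
        if not (0.0 < p <= 1.0):
            raise ValueError(
                f"row {row_no} of {path}: p-value out of range (0, 1]: {p}"
            )
        entries[gene] = p
    if not entries:
        raise ValueError(f"no valid rows parsed from {path}")
    return GeneScoreTable(entries=entries)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_modules(
    path: str | Path,
    dialect: str = "monet",
    source_label: str = "",
    algorithm_label: str = "",
) -> ModuleCollection:
    """Read a module file in the MONET or GMT dialect.

    MONET: one module per line — module id, then tab-separated gene ids. A
    numeric second field (a module score, which MONET emits) is detected and
    skipped when the line has at least three fields. GMT: id, description,
    then gene ids. Blank lines are skipped; a module id occurring twice is a
    hard error.
    """
    path = Path(path)
    if dialect not in ("monet", "gmt"):
        raise ValueError(f"unknown module dialect {dialect!r}")
    modules: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            mid = fields[0]
            if dialect == "gmt":
                genes = [g for g in fields[2:] if g]
            else:
                rest = fields[1:]
                if len(fields) >= 3 and rest and _is_number(rest[0]):
                    rest = rest[1:]  # MONET module score column
                genes = [g for g in rest if g]
            if not genes:
                logger.warning("line %d of %s: module %r has no genes; skipped",
                               line_no, path, mid)
                continue
            if mid in modules:
                raise ValueError(f"duplicate module id {mid!r} in {path}")
            modules[mid] = frozenset(genes)
    return ModuleCollection(
        modules=modules,
        source_label=source_label or path.stem,
        algorithm_label=algorithm_label,
    )


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read annotation gene sets in GMT format.

    Lines with fewer than three fields are skipped with a warning; a file
    from which no terms parse is an error; duplicate term ids are errors.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                logger.warning("line %d of %s: fewer than 3 fields; skipped",
                               line_no, path)
                continue
            tid, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                logger.warning("line %d of %s: term %r has no genes; skipped",
                               line_no, path, tid)
                continue
            if tid in terms:
                raise ValueError(f"duplicate term id {tid!r} in {path}")
            terms[tid] = (name, genes)
    if not terms:
        raise ValueError(f"no terms parsed from {path}")
    return AnnotationSet(terms=terms)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_gene_scores(table: GeneScoreTable, path: str | Path,
                      gene_column: str = "gene", p_column: str = "p") -> None:
    path = Path(path)
    df = pd.DataFrame(
        {gene_column: sorted(table.entries),
         p_column: [table.entries[g] for g in sorted(table.entries)]}
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_modules(collection: ModuleCollection, path: str | Path,
                  dialect: str = "monet") -> None:
    """Write a ModuleCollection in the MONET or GMT dialect (sorted, stable)."""
    if dialect not in ("monet", "gmt"):
        raise ValueError(f"unknown module dialect {dialect!r}")
    with open(path, "w") as fh:
        for mid in sorted(collection.modules):
            genes = sorted(collection.modules[mid])
            if dialect == "gmt":
                fh.write("\t".join([mid, "na", *genes]) + "\n")
            else:
                fh.write("\t".join([mid, *genes]) + "\n")


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(annotations.terms):
            name, genes = annotations.terms[tid]
            fh.write("\t".join([tid, name or "na", *sorted(genes)]) + "\n")


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_report(
    result: "FishnetResult",
    enriched: "Iterable[EnrichedModule]",
    terms: "Iterable[EnrichedTerm]",
    path: str | Path,
    reversal_count: int | None = None,
) -> None:
    """Write the result tables into a directory (created if needed).

    Emits ``fishnet_genes.tsv``, ``significant_modules.tsv``,
    ``enriched_terms.tsv``, ``diagnostics.tsv`` and a key-value
    ``run_summary.tsv`` capturing all parameters and the seed. Row order is
    deterministic, so re-running with identical inputs and seed produces
    byte-identical tables.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "fishnet_genes.tsv", "w") as fh:
        fh.write("gene\tp\trank\tmodules\tterms\n")
        for gene in sorted(result.genes):
            prov = result.provenance.get(gene)
            if prov is None:
                fh.write(f"{gene}\tNA\tNA\t\t\n")
                continue
            fh.write(
                f"{gene}\t{_fmt(prov.p)}\t{prov.rank}\t"
                f"{';'.join(prov.module_ids)}\t{';'.join(prov.term_ids)}\n"
            )

    with open(out / "significant_modules.tsv", "w") as fh:
        fh.write("module\tsize\tstatistic\tp_raw\tp_bonferroni\tsignificant\n")
        for m in sorted(enriched, key=lambda m: (m.p_raw, m.module_id)):
            fh.write(
                f"{m.module_id}\t{m.k_effective}\t{_fmt(m.statistic)}\t"
                f"{_fmt(m.p_raw)}\t{_fmt(m.p_bonferroni)}\t{int(m.significant)}\n"
            )

    with open(out / "enriched_terms.tsv", "w") as fh:
        fh.write(
            "term\tmodule\tp_raw\tq_bh\tk_overlap\tm_term\tn_module\t"
            "n_universe\toverlap_genes\n"
        )
        for t in sorted(terms, key=lambda t: (t.module_id, t.p_raw, t.term_id)):
            fh.write(
                f"{t.term_id}\t{t.module_id}\t{_fmt(t.p_raw)}\t{_fmt(t.q_bh)}\t"
                f"{t.k_overlap}\t{t.m_term}\t{t.n_module}\t{t.n_universe}\t"
                f"{';'.join(sorted(t.overlap_genes))}\n"
            )

    with open(out / "diagnostics.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"mode\t{result.mode}\n")
        fh.write(f"accepted\t{_fmt(result.accepted)}\n")
        fh.write(f"j_final\t{_fmt(result.j_final)}\n")
        fh.write(
            f"module_p_threshold_final\t{_fmt(result.module_p_threshold_final)}\n"
        )
        fh.write(f"c0\t{_fmt(result.c0)}\n")
        fh.write(f"fdr\t{_fmt(result.fdr)}\n")
        fh.write(f"quantile\t{_fmt(result.quantile)}\n")
        fh.write(f"n_fishnet_genes\t{len(result.genes)}\n")
        fh.write(f"rank_reversal_significant_modules\t{_fmt(reversal_count)}\n")

    with open(out / "run_summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in sorted(result.config_echo().items()):
            fh.write(f"{key}\t{_fmt(value)}\n")

    if result.trace:
        with open(out / "search_trace.tsv", "w") as fh:
            fh.write("step\tj\tmodule_p_threshold\tc0\tmean_perm_count\t"
                     "fdr\tquantile\n")
            for i, row in enumerate(result.trace):
                fh.write(
                    f"{i}\t{_fmt(row.get('j'))}\t"
                    f"{_fmt(row.get('module_p_threshold'))}\t"
                    f"{_fmt(row.get('c0'))}\t{_fmt(row.get('mean_perm_count'))}\t"
                    f"{_fmt(row.get('fdr'))}\t{_fmt(row.get('quantile'))}\n"
                )
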