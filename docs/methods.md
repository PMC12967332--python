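# Methods

## Model and assumptions

The pipeline rests on one exchangeability assumption: under the null, the
assignment of P-value ranks to genes is uniform over permutations, so low-P
genes fall randomly across network modules and functional annotations. A
gene is prioritized only when three conditions hold jointly — it sits in a
module significantly enriched for low P-values, it is annotated by a
functional term over-represented in that module, and it is among the top-j
genes overall — and when the joint occurrence of such genes exceeds what the
permutation null produces.

Modules are consumed purely as gene sets: internal connectivity is never
used, so any biologically coherent gene sets (regulons, pathways) can stand
in for network modules. Annotations are flat gene sets; no ontology
structure or ancestor propagation is applied.

### Rank → chi-squared module scoring

Ranks are assigned by ascending P with ties broken by ascending gene id (a
deterministic convention, recorded in the run summary). The empirical
quantile is p̃ = r/(N+1), which keeps every quantile strictly inside (0,1);
χ²_g is the 1-df upper-tail quantile at p̃. A module's statistic is the sum
over its scored members and is referred to χ² with k degrees of freedom.
Because scoring depends only on ranks, any strictly monotone transform of
the P-values leaves every module P-value unchanged, and the total χ² mass
over the universe is a constant of N (both properties are tested).

The χ²_k reference treats member values as independent continuous
chi-squared draws. Two approximation errors exist and matter only for very
small universes: ranks are drawn without replacement, and the rank grid
truncates the chi-squared tail at isf(1/(N+1)). At N = 1000 the analytic
tail agrees with a label-permutation oracle to better than 0.01 across
module sizes up to 30 (tested); at N ≤ 50 the discrepancy can reach ~0.2
for extreme modules, with the analytic P larger — i.e. the test errs
conservative, missing enrichment rather than inventing it. The intended
operating scale is genome-wide (thousands of genes), where the
approximation is excellent.

### Over-representation analysis

For each significant module, every annotation term with overlap ≥ 2 is
tested with the exact hypergeometric upper tail; P-values are
Benjamini–Hochberg-adjusted within the module (enriched at q ≤ 0.05). The
ORA universe defaults to scored genes appearing in at least one annotation
term (the usual reference-set convention); `universe_mode="all"` uses every
scored gene. Redundancy among enriched terms is removed by deterministic
greedy clustering: terms are scanned by ascending P and kept only if the
Jaccard similarity of their overlap genes with every kept term is below 0.5.
A randomized exemplar search (affinity propagation) would serve the same
purpose; the greedy rule was chosen for reproducibility, since the
reduction exists only to cut the multiple-testing burden. Note that greedy
clustering is not monotone: tightening the threshold can occasionally admit
a term that a dropped term previously excluded.

A gene satisfies the function criterion iff it lies in the overlap set of a
kept enriched term of its own module (the strict reading: the gene itself
must carry the shared annotation).

### Permutation test

Permutations shuffle the gene → rank map, which is equivalent to permuting
raw P-values because scoring is rank-based. Permutation i uses a child seed
derived from (seed, i), so results are independent of execution order. The
top-j set B_j is always taken from the *observed* ranking, including when
intersected with permuted candidate sets. Key conventions, chosen
deliberately conservative:

* FDR_j is undefined at |C₀ⱼ| = 0 → the criteria fail and the search
  continues (the defining ratio divides by |C₀ⱼ|).
* quantile_j counts permutation values *strictly* below the observed count,
  so an all-zero tie fails rather than trivially passing.
* j starts at round(0.05·N) (half-away-from-zero, floored at j_min = 10)
  and decreases by 10 while j ≥ 10.

The module-filter variant replaces the top-j walk: candidate sets A_i(t)
are rebuilt from modules with Bonferroni-adjusted P ≤ t, with t halving
from 0.1 down to 1e−6 (the schedule is configurable as an explicit list;
geometric halving is this package's choice — only "increasingly stringent"
is inherent to the mechanism). No top-j filter applies in this mode.

Implementation note: a module's ORA outcome depends only on its member set,
never on P-values, so ORA is computed once per module and cached across all
permutations — identical by construction to recomputing it per run, and the
reason M = 200 costs well under a second at N = 1000.

## Diagnostics

`reverse_ranks` gives the gene at rank r the P-value of rank N+1−r
(an involution preserving the value multiset). If summary statistics and
modules are independent, the genes that become top-ranked after reversal
are, by hypothesis, unassociated and should not cluster: the expected
number of significant modules is the nominal family-wise rate (~5% of runs
show ≥ 1, tested at 98/100 clean). Module-correlated inputs — the
co-expression-network-from-the-same-data pathology — are flagged in ~100%
of simulated cases, and their module P-value histogram shows the
characteristic U-shape with excess mass near 1.0.

Replication evaluation uses the replication cohort's own Bonferroni
threshold 0.05/N_replication; genes absent from the replication universe
count as not replicated and are listed. Reproduction (hit in both runs) and
replication are computed independently.

## Synthetic data generator

Fixtures emulate exactly the structure the model assumes. Background genes
draw p ~ Uniform(0,1); planted modules draw from Beta(a,1) with a = 0.1
(the standard spike model for non-null P-values; median ≈ 0.001, so most
planted genes land in the top 5% of 1000), or the mirrored 1−Beta(a,1) for
clusters of large P-values. Defaults — 1000 genes, 50 disjoint modules of
10–30 genes, 100 decoy annotation terms of 10–50 genes, full
annotation alignment of the planted term — are sized so a complete M = 200
search runs in under a second; they model a scaled-down genome, not any
particular cohort. Module sizes are drawn uniformly from the range and, if
their total would exceed the universe, the largest modules are decremented
(never below the minimum) until the partition fits; a spec whose minimum
sizes cannot fit is rejected.

The dependent-pair generator gives each module a center c ~ Uniform(0,1)
and draws member P-values from Beta(1+κc, 1+κ(1−c)) with κ = 50, producing
within-module P correlation with both low and high centers; κ = 0 recovers
the independent fixture.

What the fixtures do *not* model: linkage disequilibrium, gene-gene
correlation outside modules, realistic module size/overlap distributions,
ontology structure among terms, and P-value inflation. Passing tests
therefore demonstrate calibration and recovery under the method's own
assumptions, not performance on any real cohort.

## Numerical choices and degenerate inputs

* P-values must lie in (0, 1]; p = 0 is rejected at parse time. Internal
  probabilities are clipped to [nextafter(0,1), 1].
* Modules with fewer than 3 scored members are skipped (configurable);
  zero testable modules is a hard error for enrichment but yields an empty
  candidate set in the search paths.
* The Bonferroni divisor is the number of modules actually tested, held
  constant across permutations (the module set never changes).
* All tie-breaks are lexicographic on identifiers; reruns with the same
  inputs and seed are byte-identical, and output tables are sorted.

## Known limitations

* The analytic module test is approximate at very small N (see above).
* Term redundancy reduction differs from affinity propagation, so kept-term
  lists are not comparable across implementations (the candidate gene union
  is far less sensitive).
* The permutation test assumes the module set is fixed; it does not model
  uncertainty in module detection.
* Evaluation is per (discovery, replication) pair; aggregation across many
  dataset pairs is left to scripting.
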