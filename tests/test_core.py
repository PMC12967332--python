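"""Candidate sets, permutation ensemble, and the two threshold searches."""

import numpy as np
import pytest

from fishnet import (
    AnnotationSet,
    EnrichmentParams,
    FixtureSpec,
    GeneScoreTable,
    ModuleCollection,
    PermutationConfig,
    SignalModel,
    candidate_genes,
    compute_fdr,
    compute_quantile,
    generate,
    module_filter_search,
    permute_and_collect,
    rank_filter_search,
    simple_mode,
    top_genes,
)
from fishnet.core import _Engine


class TestArithmetic:
    def test_fdr_zero_permutation_counts(self):
        assert compute_fdr(7, [0, 0, 0]) == 0.0

    def test_fdr_hand_case(self):
        assert compute_fdr(3, [2, 4]) == pytest.approx(1.0)

    def test_fdr_undefined_at_zero_candidates(self):
        assert compute_fdr(0, [1, 2]) is None

    def test_fdr_negative_is_error(self):
        with pytest.raises(ValueError):
            compute_fdr(-1, [0])

    def test_quantile_all_below(self):
        assert compute_quantile(3, [0, 1, 2]) == 1.0

    def test_quantile_ties_do_not_count(self):
        assert compute_quantile(0, [0, 0, 0]) == 0.0

    def test_quantile_hand_case(self):
        assert compute_quantile(2, [0, 1, 1, 5]) == 0.75


class TestTopGenes:
    def test_whole_universe(self, tiny_scores):
        assert top_genes(tiny_scores, 5) == frozenset(tiny_scores.entries)

    def test_nesting(self, tiny_scores):
        assert top_genes(tiny_scores, 2) <= top_genes(tiny_scores, 4)

    def test_tie_break(self):
        table = GeneScoreTable(entries={"c": 0.5, "a": 0.5, "b": 0.5})
        assert top_genes(table, 2) == frozenset({"a", "b"})

    def test_out_of_range_j(self, tiny_scores):
        with pytest.raises(ValueError):
            top_genes(tiny_scores, 6)
        with pytest.raises(ValueError):
            top_genes(tiny_scores, 0)


class TestConfig:
    def test_m_zero_rejected(self):
        with pytest.raises(ValueError):
            PermutationConfig(M=0)

    def test_out_of_range_thresholds_warn(self):
        with pytest.warns(UserWarning):
            PermutationConfig(fdr_threshold=0.5)
        with pytest.warns(UserWarning):
            PermutationConfig(quantile_threshold=0.5)


class TestCandidateGenes:
    def test_no_significant_module_gives_empty_set(self):
        scores, modules, annotations, _ = generate(FixtureSpec(seed=123))
        # null fixture: almost surely no significant module at this seed
        assert candidate_genes(scores, modules, annotations) == frozenset()

    def test_criterion_two_gates_module_genes(self):
        # one overwhelmingly significant module but no annotation overlap:
        # its genes must not become candidates
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(100)]
        p = rng.uniform(0.2, 1.0, 100)
        p[:10] = 1e-8
        scores = GeneScoreTable(entries=dict(zip(genes, p)))
        modules = ModuleCollection(modules={"sig": frozenset(genes[:10])})
        annotations = AnnotationSet(
            terms={"T1": ("t", frozenset(genes[50:70]))}
        )
        assert candidate_genes(scores, modules, annotations) == frozenset()

    def test_planted_fixture_recovers_module(self, planted_fixture):
        scores, modules, annotations, truth = planted_fixture
        a0 = candidate_genes(scores, modules, annotations)
        planted = set().union(*truth.values())
        assert a0 == frozenset(planted & scores.genes())


class TestEnsemble:
    def test_determinism_same_seed(self, planted_fixture, planted_config):
        scores, modules, annotations, _ = planted_fixture
        a = permute_and_collect(scores, modules, annotations, planted_config)
        b = permute_and_collect(scores, modules, annotations, planted_config)
        assert a.observed == b.observed
        assert a.permuted == b.permuted
        assert a.perm_sig_module_counts == b.perm_sig_module_counts

    def test_candidates_lie_in_significant_annotated_modules(
        self, planted_fixture, planted_config
    ):
        scores, modules, annotations, _ = planted_fixture
        ens = permute_and_collect(scores, modules, annotations, planted_config)
        assert len(ens.permuted) == planted_config.M
        for g in ens.observed:
            prov = ens.provenance[g]
            assert prov.module_ids and prov.term_ids

    def test_observed_count_not_systematically_extreme_under_null(self):
        # exchangeability: under the null the observed significant-module
        # count should exceed all permutation counts only ~ 1/(M+1) of runs
        config = PermutationConfig(M=20, seed=0)
        n_extreme = 0
        n_runs = 40
        for seed in range(n_runs):
            scores, modules, annotations, _ = generate(
                FixtureSpec(n_genes=300, n_modules=15, seed=40_000 + seed)
            )
            ens = permute_and_collect(scores, modules, annotations,
                                      PermutationConfig(M=20, seed=seed))
            sig0 = len(ens.observed)
            obs_count = sum(
                1 for m in ens.observed_modules if m.significant
            )
            n_extreme += obs_count > max(ens.perm_sig_module_counts)
        # expected ~ n_runs/21 ≈ 2; allow generous binomial slack
        assert n_extreme <= 8


class TestRankFilterSearch:
    def test_empty_candidates_rejects_immediately(self, tiny_scores):
        from fishnet.core import CandidateEnsemble
        ens = CandidateEnsemble(observed=frozenset(),
                                permuted=[frozenset()] * 5,
                                perm_sig_module_counts=[0] * 5)
        res = rank_filter_search(ens, tiny_scores, PermutationConfig(M=5))
        assert res.accepted is False and not res.genes and not res.trace

    def test_planted_fixture_accepts_at_first_j(self, planted_fixture,
                                                planted_config):
        scores, modules, annotations, truth = planted_fixture
        ens = permute_and_collect(scores, modules, annotations, planted_config)
        res = rank_filter_search(ens, scores, planted_config)
        assert res.accepted is True
        assert res.j_final == 50  # round(0.05 * 1000): accepted immediately
        assert len(res.trace) == 1
        assert res.genes <= ens.observed
        assert res.genes == ens.observed & top_genes(scores, res.j_final)

    def test_result_genes_nested_in_simple_mode(self, planted_fixture,
                                                planted_config):
        scores, modules, annotations, _ = planted_fixture
        ens = permute_and_collect(scores, modules, annotations, planted_config)
        res = rank_filter_search(ens, scores, planted_config)
        simple = simple_mode(scores, modules, annotations, planted_config)
        assert res.genes <= simple.genes

    def test_full_result_determinism(self, planted_fixture, planted_config):
        scores, modules, annotations, _ = planted_fixture
        results = []
        for _ in range(2):
            ens = permute_and_collect(scores, modules, annotations,
                                      planted_config)
            results.append(rank_filter_search(ens, scores, planted_config))
        a, b = results
        assert (a.genes, a.j_final, a.fdr, a.quantile, a.trace) == \
               (b.genes, b.j_final, b.fdr, b.quantile, b.trace)


class TestModuleFilterSearch:
    def test_planted_fixture_accepted(self, planted_fixture, planted_config):
        scores, modules, annotations, truth = planted_fixture
        res = module_filter_search(scores, modules, annotations,
                                   planted_config)
        assert res.accepted is True
        assert res.module_p_threshold_final is not None
        planted = set().union(*truth.values())
        assert res.genes <= frozenset(planted)

    def test_candidate_sets_nested_under_tightening(self, planted_fixture,
                                                    planted_config):
        scores, modules, annotations, _ = planted_fixture
        engine = _Engine(scores, modules, annotations, EnrichmentParams())
        pb = np.minimum(1.0, engine.module_p() * engine.n_tested)
        previous = None
        for t in (0.1, 0.05, 0.01, 0.001):
            current = engine.candidate_set(np.flatnonzero(pb <= t))
            if previous is not None:
                assert current <= previous
            previous = current

    def test_rejects_when_schedule_exhausted_on_null(self):
        scores, modules, annotations, _ = generate(FixtureSpec(seed=123))
        res = module_filter_search(scores, modules, annotations,
                                   PermutationConfig(M=20, seed=123))
        assert res.accepted is False and not res.genes

    def test_two_modes_agree_on_planted_signal(self, planted_fixture,
                                               planted_config):
        scores, modules, annotations, truth = planted_fixture
        ens = permute_and_collect(scores, modules, annotations, planted_config)
        rank_res = rank_filter_search(ens, scores, planted_config)
        mod_res = module_filter_search(scores, modules, annotations,
                                       planted_config)
        planted = set().union(*truth.values())
        top = top_genes(scores, rank_res.j_final)
        expected = frozenset(planted) & ens.observed & top
        assert expected <= (rank_res.genes & mod_res.genes)


class TestSimpleMode:
    def test_empty_candidates_empty_result(self):
        scores, modules, annotations, _ = generate(FixtureSpec(seed=123))
        res = simple_mode(scores, modules, annotations)
        assert res.genes == frozenset()
        assert res.fdr is None and res.quantile is None
        assert res.accepted is None

    def test_planted_fixture_top_five_percent(self, planted_fixture):
        scores, modules, annotations, _ = planted_fixture
        res = simple_mode(scores, modules, annotations)
        a0 = candidate_genes(scores, modules, annotations)
        assert res.genes == a0 & top_genes(scores, 50)
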