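import itertools
import math

import numpy as np
import pytest

from coevomap.errors import CoevomapError, InfeasibleError
from coevomap.io import AlignedFamily
from coevomap.lagrangian import (
    SolverConfig,
    dual_bound,
    local_profit,
    primal_from_dual,
    solve,
)
from coevomap.matching import (
    best_matching_by_enumeration,
    build_graph,
    enumerate_max_matchings,
    log_likelihood,
)
from coevomap.model import ParalogMatchingModel
from coevomap.scoring import build_score_table
from coevomap.simulate import SynthConfig, generate
from tests.conftest import random_small_config


def _uniform_instance(paralogs=2, species=2):
    """All sequences identical -> every unit scores log 1 = 0."""
    seqs_a, seqs_b, sp_a, sp_b = [], [], {}, {}
    for t in range(species):
        sp = f"S{t}"
        for m in range(paralogs):
            sid = f"a{t}x{m}_{sp}"
            seqs_a.append((sid, "MKVLTA"))
            sp_a[sid] = sp
            sid = f"b{t}x{m}_{sp}"
            seqs_b.append((sid, "ADEFGH"))
            sp_b[sid] = sp
    fam_a = AlignedFamily("ua", tuple(seqs_a), sp_a)
    fam_b = AlignedFamily("ub", tuple(seqs_b), sp_b)
    return ParalogMatchingModel(fam_a, fam_b)


class TestLocalProfit:
    def test_no_partners_gives_zero(self):
        fam_a = AlignedFamily("a", (("a1_S", "MK"),), {"a1_S": "S"})
        fam_b = AlignedFamily("b", (("b1_S", "MR"),), {"b1_S": "S"})
        graph = build_graph(fam_a, fam_b)
        table = build_score_table(fam_a, fam_b, graph)
        assert local_profit(0, 0, None, table) == 0.0

    def test_single_partner_returns_its_weight(self):
        model = _uniform_instance(paralogs=1, species=2)
        table = model.table
        (q,) = table.log_f
        assert local_profit(0, 0, None, table) == pytest.approx(table.w(q))

    def test_matches_exhaustive_partner_matching(self, small_model):
        model, _ = small_model
        table, graph = model.table, model.graph
        for i, k in graph.edges[:6]:
            partners = [
                (j, l)
                for (j, l) in graph.edges
                if j != i and l != k
            ]
            best = 0.0
            for size in range(1, min(len(partners), 6) + 1):
                for combo in itertools.combinations(partners, size):
                    js = [j for j, _ in combo]
                    ls = [l for _, l in combo]
                    if len(set(js)) < size or len(set(ls)) < size:
                        continue
                    val = sum(
                        table.w(table.quad_of((i, k), (j, l))) for j, l in combo
                    )
                    best = max(best, val)
            assert local_profit(i, k, None, table) == pytest.approx(best)

    def test_non_edge_rejected(self, small_model):
        model, _ = small_model
        non_edges = set(
            itertools.product(range(len(model.graph.nodes_a)),
                              range(len(model.graph.nodes_b)))
        ) - set(model.graph.edges)
        i, k = sorted(non_edges)[0]
        with pytest.raises(CoevomapError):
            local_profit(i, k, None, model.table)


class TestDualBound:
    def test_single_edge_instance(self):
        model = _uniform_instance(paralogs=1, species=1)
        value, x, y = dual_bound(None, model.table, model.graph)
        assert value == pytest.approx(0.0)
        assert len(x) == 1

    def test_zero_lambda_dominates_exact_optimum(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            fam_a, fam_b, _ = generate(random_small_config(rng, max_paralogs=3))
            model = ParalogMatchingModel(fam_a, fam_b)
            _, opt = best_matching_by_enumeration(model.graph, model.table)
            value, x, _ = dual_bound(None, model.table, model.graph)
            assert value >= opt - 1e-9
            _, lower = primal_from_dual(x, model.table)
            assert lower <= opt + 1e-9

    def test_bound_valid_for_random_multipliers(self, small_model):
        """Weak duality must hold for arbitrary multiplier vectors."""
        model, _ = small_model
        _, opt = best_matching_by_enumeration(model.graph, model.table)
        rng = np.random.default_rng(11)
        quads = sorted(model.table.log_f)
        for scale in (0.1, 1.0, 5.0):
            lam = {q: float(rng.normal(0, scale)) for q in quads}
            value, x, _ = dual_bound(lam, model.table, model.graph)
            assert value >= opt - 1e-9
            _, lower = primal_from_dual(x, model.table)
            assert lower <= opt + 1e-9

    def test_master_matching_has_maximum_cardinality(self, small_model):
        model, _ = small_model
        _, x, _ = dual_bound(None, model.table, model.graph)
        assert len(x) == model.graph.n


class TestPrimalFromDual:
    def test_undersized_master_rejected(self, small_model):
        model, truth = small_model
        from coevomap.matching import Matching

        with pytest.raises(CoevomapError):
            primal_from_dual(Matching(truth.pairs[:1]), model.table)

    def test_returns_matching_loglik(self, small_model):
        model, truth = small_model
        m, val = primal_from_dual(truth, model.table)
        assert m is truth
        assert val == pytest.approx(log_likelihood(truth, model.table))


class TestSolve:
    def test_uniform_scores_close_gap_at_first_iteration(self):
        model = _uniform_instance(paralogs=2, species=2)
        res = solve(model.graph, model.table, max_iter=50)
        assert res.proved_optimal
        assert res.iterations == 1
        assert res.lower_bound == pytest.approx(0.0, abs=1e-9)
        assert res.upper_bound == pytest.approx(0.0, abs=1e-9)

    def test_empty_graph_is_infeasible(self):
        fam_a = AlignedFamily("a", (("a1_S1", "MK"),), {"a1_S1": "S1"})
        fam_b = AlignedFamily("b", (("b1_S2", "MR"),), {"b1_S2": "S2"})
        with pytest.raises(InfeasibleError):
            build_graph(fam_a, fam_b)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(314159)
        proved = 0
        n_instances = 30
        for _ in range(n_instances):
            fam_a, fam_b, _ = generate(random_small_config(rng))
            model = ParalogMatchingModel(fam_a, fam_b)
            _, opt = best_matching_by_enumeration(model.graph, model.table)
            res = solve(model.graph, model.table, max_iter=500, time_limit=60.0)
            assert res.lower_bound - 1e-9 <= opt <= res.upper_bound + 1e-9
            if res.proved_optimal:
                proved += 1
                assert abs(res.lower_bound - opt) <= 1e-6
        assert proved >= 0.9 * n_instances

    def test_trace_bounds_are_monotone_and_sandwiched(self, small_model):
        model, _ = small_model
        res = solve(model.graph, model.table, max_iter=200)
        lows = [lo for lo, _ in res.trace]
        ups = [up for _, up in res.trace]
        assert all(b >= a - 1e-12 for a, b in zip(lows, lows[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(ups, ups[1:]))
        assert all(lo <= up + 1e-9 for lo, up in res.trace)

    def test_deterministic_given_config(self, small_model):
        model, _ = small_model
        cfg = SolverConfig(max_iter=120, seed=3)
        r1 = solve(model.graph, model.table, cfg)
        r2 = solve(model.graph, model.table, SolverConfig(max_iter=120, seed=3))
        assert r1.matching == r2.matching
        assert r1.lower_bound == r2.lower_bound
        assert r1.upper_bound == r2.upper_bound
        assert r1.trace == r2.trace

    def test_recovers_planted_matching_under_strong_signal(self):
        fam_a, fam_b, truth = generate(
            SynthConfig(
                n_species=3,
                paralogs_per_species=(3, 3),
                seq_length=220,
                decoy_rate_jitter=0.35,
                seed=77,
            )
        )
        model = ParalogMatchingModel(fam_a, fam_b)
        res = solve(model.graph, model.table, max_iter=300)
        # the solver must return the exact ML optimum with a proof ...
        best, opt = best_matching_by_enumeration(model.graph, model.table)
        assert res.proved_optimal
        assert set(res.matching.pairs) == set(best.pairs)
        # ... and under a strong signal that optimum is close to the truth
        # (rate draws can still collide for individual paralog slots)
        overlap = res.matching.intersection_size(truth)
        assert overlap >= len(truth) - 2

    def test_relative_gap_definition(self, small_model):
        model, _ = small_model
        res = solve(model.graph, model.table, max_iter=1, gap_tol=0.0,
                    dual_descent_every=0, local_search=False)
        if res.upper_bound - res.lower_bound > 1e-12:
            assert res.relative_gap == pytest.approx(
                (res.upper_bound - res.lower_bound) / abs(res.lower_bound)
            )
        else:
            assert res.relative_gap == 0.0
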