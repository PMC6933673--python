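from math import comb

import numpy as np
import pytest

from oracles import exact_hypergeom_upper
from tfmodminer.evaluation import (
    _haldane_anscombe_or,
    compare_enrichment,
    expression_coherence_comparison,
    go_enrichment,
    interaction_prevalence,
)
from tfmodminer.io import AnnotationMap, ConfidenceNetwork, ExpressionMatrix


def _ann(d):
    return AnnotationMap(mapping={k: frozenset(v) for k, v in d.items()})


class TestGoEnrichment:
    def test_perfect_enrichment_probability(self):
        genome = {f"g{i}" for i in range(20)}
        targets = {f"g{i}" for i in range(5)}
        ann = _ann({g: {"TERM"} for g in targets})
        results, summary = go_enrichment(targets, ann, genome, alpha=0.05)
        (r,) = results
        assert r.p_value == pytest.approx(1 / comb(20, 5))
        assert r.significant
        assert summary.n_significant == 1
        assert summary.log_score == pytest.approx(-np.log10(1 / 15504))

    def test_genome_wide_term_never_significant(self):
        genome = {f"g{i}" for i in range(30)}
        ann = _ann({g: {"EVERYWHERE"} for g in genome})
        results, summary = go_enrichment(set(list(genome)[:6]), ann, genome)
        (r,) = results
        assert r.p_value == pytest.approx(1.0)
        assert summary.log_score == 0.0 and summary.odds_ratio_score == 0.0

    def test_pvalues_match_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        genome = [f"g{i}" for i in range(40)]
        ann = _ann(
            {g: {t for t in ("A", "B", "C") if rng.uniform() < 0.3} for g in genome}
        )
        targets = set(rng.choice(genome, size=10, replace=False))
        results, _ = go_enrichment(targets, ann, set(genome))
        for r in results:
            assert r.p_value == pytest.approx(
                exact_hypergeom_upper(r.k, r.N, r.K, r.n), rel=1e-9
            )
            assert r.q_value >= r.p_value - 1e-15

    def test_targets_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment({"x"}, _ann({}), {"a", "b"})

    def test_odds_ratio_haldane_anscombe(self):
        # k=3, n=5, K=4, N=20: cells (3.5, 2.5, 1.5, 14.5)
        assert _haldane_anscombe_or(3, 5, 4, 20) == pytest.approx(
            (3.5 * 14.5) / (1.5 * 2.5)
        )
        # zero cells stay finite
        assert np.isfinite(_haldane_anscombe_or(5, 5, 5, 20))

    def test_ancestor_propagation(self):
        genome = {f"g{i}" for i in range(10)}
        ann = _ann({"g0": {"child"}, "g1": {"child"}, "g2": {"parent"}})
        parents = {"child": {"parent"}}
        results, _ = go_enrichment(
            {"g0", "g1"}, ann, genome, parents=parents
        )
        by_term = {r.term: r for r in results}
        assert by_term["parent"].k == 2 and by_term["parent"].K == 3


class TestCompareEnrichment:
    def test_equal_sets_tie(self):
        genome = {f"g{i}" for i in range(20)}
        ann = _ann({g: {"T"} for g in list(genome)[:5]})
        s = set(list(genome)[:5])
        v = compare_enrichment(s, s, ann, genome)[None]
        assert v == {"log_score": "tie", "odds_ratio_score": "tie"}

    def test_enriched_block_beats_random(self):
        rng = np.random.default_rng(7)
        genome = [f"g{i}" for i in range(60)]
        block = set(genome[:8])
        ann = _ann({g: {"BLOCK"} for g in block})
        random_set = set(rng.choice(genome[8:], size=8, replace=False))
        v = compare_enrichment(block, random_set, ann, set(genome))[None]
        assert v["log_score"] == "A"

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        genome = [f"g{i}" for i in range(40)]
        ann = _ann(
            {g: {t for t in ("A", "B") if rng.uniform() < 0.4} for g in genome}
        )
        sa = set(genome[:7])
        sb = set(genome[20:30])
        fwd = compare_enrichment(sa, sb, ann, set(genome))[None]
        rev = compare_enrichment(sb, sa, ann, set(genome))[None]
        flip = {"A": "B", "B": "A", "tie": "tie"}
        assert rev["log_score"] == flip[fwd["log_score"]]
        assert rev["odds_ratio_score"] == flip[fwd["odds_ratio_score"]]


class TestInteractionPrevalence:
    def test_no_adjacent_targets_core_empty(self):
        genome = {f"g{i}" for i in range(10)}
        net = ConfidenceNetwork([("g0", "g5", 1.0)])
        res = interaction_prevalence({"g0", "g1"}, net, genome)
        assert res.core == frozenset() and res.p_value == 1.0

    def test_clique_targets_exact_probability(self):
        genome = {f"g{i}" for i in range(100)}
        clique = ["g0", "g1", "g2", "g3"]
        edges = [
            (a, b, 1.0) for i, a in enumerate(clique) for b in clique[i + 1 :]
        ]
        net = ConfidenceNetwork(edges)
        res = interaction_prevalence(set(clique), net, genome)
        assert res.core == frozenset(clique)
        assert res.neighbors == frozenset()
        assert res.p_value == pytest.approx(1 / comb(100, 4))
        assert res.enriched

    def test_complete_graph_uninformative(self):
        genome = [f"g{i}" for i in range(12)]
        edges = [
            (a, b, 1.0) for i, a in enumerate(genome) for b in genome[i + 1 :]
        ]
        net = ConfidenceNetwork(edges)
        res = interaction_prevalence(set(genome[:5]), net, set(genome))
        assert res.complex == frozenset(genome)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        genome = {f"g{i}" for i in range(30)}
        net = ConfidenceNetwork(
            [("g0", "g1", 1.0), ("g1", "g2", 1.0), ("g2", "g9", 1.0)]
        )
        targets = {"g0", "g1", "g2", "g5"}
        res = interaction_prevalence(targets, net, genome)
        k, K, n = len(res.core), len(res.complex), len(targets)
        assert res.p_value == pytest.approx(
            exact_hypergeom_upper(k, 30, K, n), rel=1e-9
        )


class TestExpressionCoherenceComparison:
    def _expr(self, rows, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            rows=rows,
            conditions=[f"c{i}" for i in range(values.shape[1])],
            values=values,
        )

    def test_coherent_set_wins(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=12)
        coherent = [base * s + rng.normal(scale=0.01, size=12) for s in (1, 2, 3, 4, 5)]
        noise = [rng.normal(size=12) for _ in range(5)]
        rows = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        expr = self._expr(rows, np.vstack(coherent + noise))
        res = expression_coherence_comparison(
            {f"a{i}" for i in range(5)},
            {f"b{i}" for i in range(5)},
            {"cond": expr},
        )
        assert res.wins_a == 1 and res.wins_b == 0

    def test_identical_sets_win_nothing(self):
        rng = np.random.default_rng(2)
        rows = [f"g{i}" for i in range(4)]
        expr = self._expr(rows, rng.normal(size=(4, 10)))
        res = expression_coherence_comparison(set(rows), set(rows), {"c": expr})
        assert res.wins_a == 0 and res.wins_b == 0

    def test_condition_with_singleton_set_skipped(self):
        rng = np.random.default_rng(3)
        expr_ok = self._expr(["a1", "a2", "b1", "b2"], rng.normal(size=(4, 8)))
        expr_bad = self._expr(["a1", "a2", "b1"], rng.normal(size=(3, 8)))
        res = expression_coherence_comparison(
            {"a1", "a2"}, {"b1", "b2"}, {"ok": expr_ok, "bad": expr_bad}
        )
        assert res.skipped == ["bad"]
        assert len(res.conditions) == 1

    def test_set_never_expressed_rejected(self):
        rng = np.random.default_rng(4)
        expr = self._expr(["a1", "a2"], rng.normal(size=(2, 8)))
        with pytest.raises(ValueError, match="set B"):
            expression_coherence_comparison({"a1", "a2"}, {"z1", "z2"}, {"c": expr})


def test_functional_targets_enrich_better_on_synthetic():
    """Module-inferred functional target sets match or beat the full binding
    target sets on the log enrichment score for most planted TFs."""
    from tfmodminer.pipeline import run_stages
    from tfmodminer.synthetic import SyntheticConfig, generate_dataset
    from tfmodminer.targets import infer_functional_pairs

    wins, losses = 0, 0
    for seed in range(10):
        bundle = generate_dataset(SyntheticConfig(seed=seed))
        _, _, confident, _ = run_stages(
            bundle.binding, bundle.expression, bundle.network, seed=seed
        )
        pairs = infer_functional_pairs(bundle.binding, bundle.knockout, confident)
        functional: dict[str, set[str]] = {}
        for p in pairs:
            functional.setdefault(p.tf, set()).add(p.gene)
        genome = frozenset(g for g in bundle.expression.rows if g.startswith("G"))
        planted_tfs = set().union(*(m.tfs for m in bundle.truth))
        for tf in sorted(planted_tfs & set(functional)):
            func_set = frozenset(functional[tf]) & genome
            bind_set = frozenset(bundle.binding.genes_of(tf)) & genome
            if not func_set:
                continue
            _, s_func = go_enrichment(func_set, bundle.annotations, genome)
            _, s_bind = go_enrichment(bind_set, bundle.annotations, genome)
            if s_func.log_score >= s_bind.log_score:
                wins += 1
            else:
                losses += 1
    assert wins > losses
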