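import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfmodminer.io import AnnotationMap, ExpressionMatrix, TFModule
from tfmodminer.redundancy import (
    FRSTable,
    compare_group_frs,
    dice,
    frs,
    frs_table,
    module_coherence,
)


def _ann(d):
    return AnnotationMap(mapping={k: frozenset(v) for k, v in d.items()})


class TestFRS:
    def test_identical_nonempty_sets_score_one(self):
        ann = _ann({"t": {"a", "b"}, "q": {"a", "b"}, "r": {"z"}})
        assert frs("t", ann, {"t", "q", "r"}) == 1.0

    def test_disjoint_sets_score_zero(self):
        ann = _ann({"t": {"a"}, "q": {"b"}, "r": {"c"}})
        assert frs("t", ann, {"t", "q", "r"}) == 0.0

    def test_hand_computed_dice(self):
        ann = _ann({"t": {"a", "b", "c"}, "q": {"b", "c"}})
        assert frs("t", ann, {"t", "q"}) == pytest.approx(0.8)

    def test_tf_outside_universe_rejected(self):
        ann = _ann({"t": {"a"}})
        with pytest.raises(KeyError):
            frs("z", ann, {"t"})

    def test_evidence_symmetry(self):
        """If FRS(t) is attained at q with Dice d, then FRS(q) >= d."""
        rng = np.random.default_rng(0)
        terms = [f"x{i}" for i in range(12)]
        for _ in range(25):
            catalog = {
                f"t{i}": frozenset(
                    t for t in terms if rng.uniform() < 0.3
                )
                for i in range(6)
            }
            ann = _ann(catalog)
            universe = frozenset(catalog)
            for t in universe:
                d = frs(t, ann, universe)
                for q in universe - {t}:
                    if dice(ann.terms(t), ann.terms(q)) == d:
                        assert frs(q, ann, universe) >= d - 1e-12

    @given(
        st.dictionaries(
            st.sampled_from([f"t{i}" for i in range(6)]),
            st.frozensets(st.sampled_from([f"g{i}" for i in range(8)]), max_size=8),
            min_size=2,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_exactness_of_one(self, catalog):
        ann = _ann(catalog)
        universe = frozenset(catalog)
        for t in universe:
            v = frs(t, ann, universe)
            assert 0.0 <= v <= 1.0
            twin = any(
                catalog[q] == catalog[t] and catalog[t]
                for q in universe - {t}
            )
            if twin:
                assert v == 1.0

    def test_frs_table_flags_unannotated(self):
        ann = _ann({"t": {"a"}, "q": {"a"}})
        table = frs_table(ann, {"t", "q", "bare"})
        assert table.absent == {"bare"}
        assert set(table.scores) == {"t", "q"}


class TestCompareGroupFRS:
    def _table(self, scores):
        return FRSTable(scores=scores, tf_universe=frozenset(scores))

    def test_identical_groups_null(self):
        table = self._table({"a": 0.5, "b": 0.7, "c": 0.5, "d": 0.7})
        t, p, m1, m2 = compare_group_frs({"a", "b"}, {"c", "d"}, table)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)
        assert m1 == m2

    def test_hand_computed_welch(self):
        a, b = [0.9, 0.8, 0.85], [0.2, 0.3, 0.25]
        table = self._table(
            {f"a{i}": v for i, v in enumerate(a)} | {f"b{i}": v for i, v in enumerate(b)}
        )
        t, p, _, _ = compare_group_frs({"a0", "a1", "a2"}, {"b0", "b1", "b2"}, table)
        # Welch by hand
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t_exp = (np.mean(a) - np.mean(b)) / math.sqrt(va / 3 + vb / 3)
        assert t == pytest.approx(t_exp)
        assert p < 0.001

    def test_degenerate_groups_rejected(self):
        table = self._table({"a": 0.5, "b": 0.6, "c": 0.7})
        with pytest.raises(ValueError, match=">= 2"):
            compare_group_frs({"a", "b"}, set(), table)
        flat = self._table({"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.5})
        with pytest.raises(ValueError, match="zero variance"):
            compare_group_frs({"a", "b"}, {"c", "d"}, flat)

    def test_planted_module_tfs_more_redundant(self):
        """Shared annotation blocks push planted-module TFs above background."""
        from tfmodminer.synthetic import SyntheticConfig, generate_dataset

        deltas = []
        for seed in range(20):
            bundle = generate_dataset(SyntheticConfig(seed=seed))
            tf_universe = frozenset(
                r for r in bundle.expression.rows if r.startswith("TF")
            )
            table = frs_table(bundle.annotations, tf_universe)
            planted = set().union(*(m.tfs for m in bundle.truth))
            background = tf_universe - planted
            mean_p = np.mean([table.scores[t] for t in planted])
            mean_b = np.mean([table.scores[t] for t in background if t in table.scores])
            deltas.append(mean_p - mean_b)
        assert np.mean(deltas) > 0


class TestModuleCoherence:
    def _module(self, tfs):
        return TFModule(
            gene="g",
            terminals=frozenset(tfs),
            mediators=frozenset(),
            edges=frozenset(),
            cost=0.0,
        )

    def _expr(self, rows, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            rows=rows,
            conditions=[f"c{i}" for i in range(values.shape[1])],
            values=values,
        )

    def test_identical_profiles_score_one(self):
        expr = self._expr(["a", "b"], [[1, 2, 3, 4], [2, 4, 6, 8]])
        res = module_coherence(self._module({"a", "b"}), expr)
        assert res.coherence == pytest.approx(1.0)
        assert res.n_pairs == 1

    def test_orthogonal_profiles_score_zero(self):
        expr = self._expr(["a", "b"], [[1, -1, 1, -1], [1, 1, -1, -1]])
        res = module_coherence(self._module({"a", "b"}), expr)
        assert res.coherence == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_squared_correlations(self):
        # a == b exactly (r=1); c orthogonal to both (r=0)
        expr = self._expr(
            ["a", "b", "c"],
            [[1, -1, 1, -1], [2, -2, 2, -2], [1, 1, -1, -1]],
        )
        res = module_coherence(self._module({"a", "b", "c"}), expr)
        assert res.coherence == pytest.approx(1 / 3)
        assert res.n_pairs == 3

    def test_fewer_than_two_expressed_terminals_rejected(self):
        expr = self._expr(["a"], [[1, 2, 3]])
        with pytest.raises(ValueError, match="fewer than two"):
            module_coherence(self._module({"a", "zzz"}), expr)

    def test_bounds_and_condition_permutation_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(4, 30))
        rows = list("abcd")
        res1 = module_coherence(self._module(rows), self._expr(rows, values))
        perm = rng.permutation(30)
        res2 = module_coherence(self._module(rows), self._expr(rows, values[:, perm]))
        assert 0.0 <= res1.coherence <= 1.0
        assert res1.coherence == pytest.approx(res2.coherence)

    def test_pairwise_complete_over_missing(self):
        expr = self._expr(
            ["a", "b"], [[1, 2, 3, np.nan], [2, 4, 6, 100.0]]
        )
        res = module_coherence(self._module({"a", "b"}), expr)
        assert res.coherence == pytest.approx(1.0)
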