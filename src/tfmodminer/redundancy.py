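"""Functional redundancy scoring and module expression coherence.

The functional redundancy score (FRS) of a TF t is the maximum Dice
coefficient between its annotation-term set and that of any other TF in
the universe:

    FRS(t) = max_{q != t}  2 |F_t ∩ F_q| / (|F_t| + |F_q|)

where F_t is the set of terms (e.g. GO ids) annotated to t.  FRS lies in
[0, 1]; a score of 1 means some other TF carries an identical, non-empty
annotation set — a perfect functional backup.  TFs that participate in
regulatory modules are expected to score higher than TFs that do not,
which is checked with a one-sided Welch t-test.

Module coherence is the mean of squared Pearson correlations between the
expression profiles of every TF pair in a module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .io import AnnotationMap, ExpressionMatrix, TFModule


@dataclass
class FRSTable:
    """Per-TF functional redundancy scores over a fixed TF universe.

    TFs without annotation data are listed in ``absent`` rather than
    given a score.
    """

    scores: dict[str, float]
    tf_universe: frozenset[str]
    absent: frozenset[str] = frozenset()

    def __getitem__(self, tf: str) -> float:
        return self.scores[tf]


def dice(a: frozenset[str], b: frozenset[str]) -> float:
    """Dice coefficient of two term sets; a pair of empty sets scores 0."""
    denom = len(a) + len(b)
    if denom == 0:
        return 0.0
    return 2.0 * len(a & b) / denom


def frs(
    t: str,
    annotations: AnnotationMap,
    tf_universe: frozenset[str] | set[str],
    aspect: str | None = None,
) -> float:
    """Maximum Dice coefficient between t's term set and any other TF's."""
    if t not in tf_universe:
        raise KeyError(f"TF {t!r} not in the supplied universe")
    f_t = annotations.terms(t, aspect)
    best = 0.0
    for q in tf_universe:
        if q == t:
            continue
        best = max(best, dice(f_t, annotations.terms(q, aspect)))
    return best


def frs_table(
    annotations: AnnotationMap,
    tf_universe: frozenset[str] | set[str],
    aspect: str | None = None,
) -> FRSTable:
    """FRS for every TF in the universe that has annotation data."""
    universe = frozenset(tf_universe)
    absent = frozenset(t for t in universe if not annotations.terms(t, aspect))
    scores = {t: frs(t, annotations, universe, aspect) for t in universe - absent}
    return FRSTable(scores=scores, tf_universe=universe, absent=absent)


def compare_group_frs(
    module_tfs: frozenset[str] | set[str],
    other_tfs: frozenset[str] | set[str],
    table: FRSTable,
) -> tuple[float, float, float, float]:
    """One-sided Welch t-test: do module-member TFs score higher?

    Returns ``(t_statistic, p_value, module_mean, other_mean)``.  TFs
    without scores are dropped; each remaining group needs at least two
    members and the pooled sample some variance.
    """
    a = np.array([table.scores[t] for t in sorted(module_tfs) if t in table.scores])
    b = np.array([table.scores[t] for t in sorted(other_tfs) if t in table.scores])
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"need >= 2 scored TFs per group, got {a.size} module and {b.size} other"
        )
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        raise ValueError("both groups have zero variance; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue), float(a.mean()), float(b.mean())


@dataclass
class CoherenceResult:
    module: TFModule
    coherence: float
    n_pairs: int


def _pairwise_complete_r(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok], y[ok]
    if xv.std() == 0.0 or yv.std() == 0.0:
        return np.nan
    return float(np.corrcoef(xv, yv)[0, 1])


def module_coherence(module: TFModule, expr: ExpressionMatrix) -> CoherenceResult:
    """Mean squared Pearson correlation over all terminal-TF pairs.

    Correlations use pairwise-complete conditions; pairs whose overlap is
    degenerate (fewer than two shared conditions, or a constant profile)
    are excluded from the mean.
    """
    tfs = sorted(t for t in module.terminals if t in expr)
    if len(tfs) < 2:
        raise ValueError(
            f"module for gene {module.gene!r} has fewer than two terminals "
            "with expression rows"
        )
    r2 = []
    for a, b in combinations(tfs, 2):
        r = _pairwise_complete_r(expr.row(a), expr.row(b))
        if not np.isnan(r):
            r2.append(r * r)
    n_pairs = len(tfs) * (len(tfs) - 1) // 2
    coherence = float(np.mean(r2)) if r2 else 0.0
    return CoherenceResult(module=module, coherence=coherence, n_pairs=n_pairs)
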