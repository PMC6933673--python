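"""Biological-significance evaluation of TF target gene sets.

Three suites compare a TF's module-inferred functional target set with a
reference set (typically its full binding target set):

* **GO enrichment** — per-term upper-tail hypergeometric tests with BH
  correction; summarised as a log enrichment score (sum of -log10 p over
  significant terms) and an odds-ratio score (sum of Haldane-Anscombe
  corrected odds ratios over significant terms).
* **Protein-interaction prevalence** — targets with a physical
  interaction to another target form a "core"; the core plus its
  non-target neighbors form the "complex"; a hypergeometric test asks
  whether a random gene set of the same size would capture that many
  complex members.
* **Expression coherence** — within-set pairwise squared Pearson
  correlations compared across sets per condition dataset with one-tailed
  rank-sum tests, BH-corrected; a condition is "won" by the set whose
  test is significant while the mirror test is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap, ConfidenceNetwork, ExpressionMatrix


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    term: str
    k: int  # targets carrying the term
    n: int  # target-set size
    K: int  # genome genes carrying the term
    N: int  # genome size
    p_value: float
    q_value: float = 1.0
    odds_ratio: float = 0.0
    significant: bool = False


@dataclass
class EnrichmentSummary:
    log_score: float
    odds_ratio_score: float
    n_significant: int


def _haldane_anscombe_or(k: int, n: int, K: int, N: int) -> float:
    """Odds ratio of the 2x2 target/term table with the 1/2 correction."""
    a = k + 0.5
    b = n - k + 0.5
    c = K - k + 0.5
    d = N - K - n + k + 0.5
    return float(a * d / (c * b))


def go_enrichment(
    targets: frozenset[str] | set[str],
    annotations: AnnotationMap,
    genome: frozenset[str] | set[str],
    alpha: float = 0.05,
    aspect: str | None = None,
    parents: dict[str, set[str]] | None = None,
) -> tuple[list[EnrichmentResult], EnrichmentSummary]:
    """Hypergeometric term enrichment of a target set within a genome.

    Only terms annotating at least one target are tested; BH correction
    runs across that term universe.  ``parents`` optionally supplies a
    term -> parents table for true-path propagation of annotations before
    testing.
    """
    targets = frozenset(targets)
    genome = frozenset(genome)
    if not targets <= genome:
        raise ValueError("targets must be a subset of the genome")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    def gene_terms(g: str) -> frozenset[str]:
        ts = annotations.terms(g, aspect)
        if parents:
            out = set(ts)
            frontier = set(ts)
            while frontier:
                nxt: set[str] = set()
                for t in frontier:
                    nxt |= parents.get(t, set()) - out
                out |= nxt
                frontier = nxt
            return frozenset(out)
        return ts

    term_genome: dict[str, int] = {}
    term_targets: dict[str, int] = {}
    for g in genome:
        for t in gene_terms(g):
            term_genome[t] = term_genome.get(t, 0) + 1
            if g in targets:
                term_targets[t] = term_targets.get(t, 0) + 1

    N, n = len(genome), len(targets)
    results: list[EnrichmentResult] = []
    for term in sorted(term_targets):
        k, K = term_targets[term], term_genome[term]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term=term,
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=min(p, 1.0),
                odds_ratio=_haldane_anscombe_or(k, n, K, N),
            )
        )
    if results:
        _, qs, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, q in zip(results, qs):
            r.q_value = float(max(q, r.p_value))
            r.significant = r.q_value <= alpha
    sig = [r for r in results if r.significant]
    summary = EnrichmentSummary(
        log_score=float(sum(-np.log10(max(r.p_value, 1e-300)) for r in sig)),
        odds_ratio_score=float(sum(r.odds_ratio for r in sig)),
        n_significant=len(sig),
    )
    return results, summary


def compare_enrichment(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    annotations: AnnotationMap,
    genome: frozenset[str] | set[str],
    alpha: float = 0.05,
    aspects: list[str | None] | None = None,
) -> dict[str | None, dict[str, str]]:
    """Per-aspect verdicts on which set scores higher on each summary metric.

    Returns ``{aspect: {"log_score": "A"|"B"|"tie", "odds_ratio_score": ...}}``.
    """
    verdicts: dict[str | None, dict[str, str]] = {}
    for aspect in aspects if aspects is not None else [None]:
        _, sa = go_enrichment(set_a, annotations, genome, alpha, aspect)
        _, sb = go_enrichment(set_b, annotations, genome, alpha, aspect)
        verdicts[aspect] = {
            "log_score": (
                "A" if sa.log_score > sb.log_score
                else "B" if sb.log_score > sa.log_score
                else "tie"
            ),
            "odds_ratio_score": (
                "A" if sa.odds_ratio_score > sb.odds_ratio_score
                else "B" if sb.odds_ratio_score > sa.odds_ratio_score
                else "tie"
            ),
        }
    return verdicts


# ---------------------------------------------------------------------------
# protein-interaction prevalence
# ---------------------------------------------------------------------------


@dataclass
class ComplexDecomposition:
    core: frozenset[str]
    neighbors: frozenset[str]
    p_value: float
    enriched: bool

    @property
    def complex(self) -> frozenset[str]:
        return self.core | self.neighbors


def interaction_prevalence(
    targets: frozenset[str] | set[str],
    physical_edges: ConfidenceNetwork,
    genome: frozenset[str] | set[str],
    alpha: float = 0.05,
) -> ComplexDecomposition:
    """Core/neighbor complex decomposition with a hypergeometric prevalence
    test.

    The core is the set of targets physically interacting with another
    target; neighbors are non-targets adjacent to a core gene.  The
    p-value is the upper-tail probability that a uniformly random gene
    set of the same size contains at least ``|core|`` members of the
    complex (population = genome, successes = complex).
    """
    targets = frozenset(targets)
    genome = frozenset(genome)
    if not targets <= genome:
        raise ValueError("targets must be a subset of the genome")
    core = frozenset(
        t
        for t in targets
        if t in physical_edges and physical_edges.neighbors(t) & (targets - {t})
    )
    neighbors = frozenset(
        nb
        for c in core
        for nb in physical_edges.neighbors(c)
        if nb not in targets and nb in genome
    )
    complex_ = core | neighbors
    if core:
        p = float(
            stats.hypergeom.sf(len(core) - 1, len(genome), len(complex_), len(targets))
        )
    else:
        p = 1.0
    return ComplexDecomposition(
        core=core, neighbors=neighbors, p_value=min(p, 1.0), enriched=p <= alpha
    )


# ---------------------------------------------------------------------------
# expression coherence comparison
# ---------------------------------------------------------------------------


@dataclass
class ConditionCoherence:
    condition: str
    p_a_greater: float
    p_b_greater: float
    q_a_greater: float = 1.0
    q_b_greater: float = 1.0
    won_by: str = "none"  # "A" | "B" | "none"
    n_pairs_a: int = 0
    n_pairs_b: int = 0


@dataclass
class CoherenceComparison:
    conditions: list[ConditionCoherence] = field(default_factory=list)
    wins_a: int = 0
    wins_b: int = 0
    skipped: list[str] = field(default_factory=list)


def _pairwise_r2(genes: list[str], expr: ExpressionMatrix) -> np.ndarray:
    vals = []
    for a, b in combinations(genes, 2):
        x, y = expr.row(a), expr.row(b)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 2:
            continue
        xv, yv = x[ok], y[ok]
        if xv.std() == 0.0 or yv.std() == 0.0:
            continue
        r = np.corrcoef(xv, yv)[0, 1]
        vals.append(r * r)
    return np.array(vals)


def expression_coherence_comparison(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    expr_by_condition: dict[str, ExpressionMatrix],
    alpha: float = 0.05,
) -> CoherenceComparison:
    """Which set is more co-expressed, condition dataset by condition dataset?

    Per condition, the within-set pairwise squared correlations of A and
    B are compared with one-tailed Wilcoxon rank-sum tests in both
    directions; BH runs across conditions per direction.  A condition is
    won by A when A's corrected test is significant at ``alpha`` and B's
    mirror test is not (and symmetrically for B).  Conditions where
    either set has fewer than two expressed genes are skipped.
    """
    out = CoherenceComparison()
    evaluated: list[ConditionCoherence] = []
    any_a, any_b = False, False
    for cond in sorted(expr_by_condition):
        expr = expr_by_condition[cond]
        genes_a = sorted(g for g in set_a if g in expr)
        genes_b = sorted(g for g in set_b if g in expr)
        if len(genes_a) >= 2:
            any_a = True
        if len(genes_b) >= 2:
            any_b = True
        if len(genes_a) < 2 or len(genes_b) < 2:
            out.skipped.append(cond)
            continue
        r2a, r2b = _pairwise_r2(genes_a, expr), _pairwise_r2(genes_b, expr)
        if r2a.size == 0 or r2b.size == 0:
            out.skipped.append(cond)
            continue
        pa = float(stats.mannwhitneyu(r2a, r2b, alternative="greater").pvalue)
        pb = float(stats.mannwhitneyu(r2b, r2a, alternative="greater").pvalue)
        evaluated.append(
            ConditionCoherence(
                condition=cond,
                p_a_greater=pa,
                p_b_greater=pb,
                n_pairs_a=int(r2a.size),
                n_pairs_b=int(r2b.size),
            )
        )
    if not any_a or not any_b:
        which = "A" if not any_a else "B"
        raise ValueError(
            f"set {which} has fewer than two expressed genes in every condition"
        )
    if evaluated:
        _, qa, _, _ = multipletests([c.p_a_greater for c in evaluated], method="fdr_bh")
        _, qb, _, _ = multipletests([c.p_b_greater for c in evaluated], method="fdr_bh")
        for c, qav, qbv in zip(evaluated, qa, qb):
            c.q_a_greater = float(max(qav, c.p_a_greater))
            c.q_b_greater = float(max(qbv, c.p_b_greater))
            a_sig = c.q_a_greater <= alpha
            b_sig = c.q_b_greater <= alpha
            if a_sig and not b_sig:
                c.won_by = "A"
            elif b_sig and not a_sig:
                c.won_by = "B"
    out.conditions = evaluated
    out.wins_a = sum(1 for c in evaluated if c.won_by == "A")
    out.wins_b = sum(1 for c in evaluated if c.won_by == "B")
    return out
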