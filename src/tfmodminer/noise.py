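"""Stage 3: confidence testing of mined modules against the whole network.

A genuine regulatory module should be wired through interactions whose
literature confidence is higher than is typical for the network, so each
module's edge confidences are compared against the confidences of ALL
network edges with a one-sided (greater) Mann-Whitney U test.  Within
each gene's group of mined modules the p-values are Benjamini-Hochberg
adjusted, and modules with q <= alpha (0.05 by default) are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ConfidenceNetwork, TFModule


@dataclass
class ConfidenceTestResult:
    module: TFModule
    u_statistic: float
    p_value: float
    q_value: float
    kept: bool


def module_confidence_pvalue(
    module: TFModule, network: ConfidenceNetwork
) -> tuple[float, float]:
    """One-sided Mann-Whitney U: are the module's edge confidences greater
    than the network's?

    The exact null distribution is used when the smaller sample has at
    most 8 observations and there are no ties; otherwise the normal
    approximation with tie correction.  A module with zero edges cannot
    show confidence support and gets p = 1 with a warning.
    """
    x = module.edge_confidences()
    if x.size == 0:
        warnings.warn("module has no edges; confidence p-value set to 1")
        return float("nan"), 1.0
    y = network.confidences()
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def fdr_filter(
    results_by_gene: dict[str, list[tuple[TFModule, float, float]]],
    alpha: float = 0.05,
) -> list[ConfidenceTestResult]:
    """Benjamini-Hochberg within each gene's module group; keep q <= alpha.

    ``results_by_gene`` maps gene -> list of (module, u_statistic, p).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    out: list[ConfidenceTestResult] = []
    for gene in sorted(results_by_gene):
        group = results_by_gene[gene]
        if not group:
            continue
        ps = np.array([p for _, _, p in group])
        _, qs, _, _ = multipletests(ps, method="fdr_bh")
        for (mod, u, p), q in zip(group, qs):
            q = float(max(q, p))  # BH never reports q below p
            kept = q <= alpha
            mod.p_value = float(p)
            mod.q_value = q
            out.append(
                ConfidenceTestResult(
                    module=mod, u_statistic=u, p_value=float(p), q_value=q, kept=kept
                )
            )
    return out


def filter_modules(
    modules: list[TFModule],
    network: ConfidenceNetwork,
    alpha: float = 0.05,
    global_fdr: bool = False,
) -> tuple[list[TFModule], list[ConfidenceTestResult]]:
    """Test every mined module and keep those passing FDR at ``alpha``.

    With ``global_fdr`` the BH correction runs across all modules at once
    instead of within each gene's group.
    """
    tested: dict[str, list[tuple[TFModule, float, float]]] = {}
    for mod in modules:
        u, p = module_confidence_pvalue(mod, network)
        key = "" if global_fdr else mod.gene
        tested.setdefault(key, []).append((mod, u, p))
    results = fdr_filter(tested, alpha=alpha)
    kept = [r.module for r in results if r.kept]
    return kept, results
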