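"""Stage 1: candidate TF-set search by PCA + k-means on expression.

TFs that act in the same regulatory module tend to share an expression
profile, so for every gene we cluster its binding TFs in a
low-dimensional expression space and propose each multi-TF cluster as a
candidate set.  Dimensionality is reduced once, globally, by projecting
every expression row onto the top principal components (three by
default); k-means is then run per gene for every k from 2 up to the
number of binding TFs, and identical TF sets arising at different k are
merged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import BindingTable, CandidateSet, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ReducedCoordinates:
    """Rows of an expression matrix projected onto the top principal axes."""

    rows: list[str]
    coords: np.ndarray  # (n_rows, n_components)
    explained_variance_fractions: list[float]

    def __post_init__(self) -> None:
        self._index = {r: i for i, r in enumerate(self.rows)}

    def __contains__(self, row: str) -> bool:
        return row in self._index

    def of(self, identifiers: list[str]) -> np.ndarray:
        return self.coords[[self._index[r] for r in identifiers]]


def reduce_expression(
    expr: ExpressionMatrix,
    n_components: int = 3,
    scale_conditions: bool = False,
) -> ReducedCoordinates:
    """Project expression rows onto the top ``n_components`` principal axes.

    Conditions (columns) are mean-centred; rows with missing values are
    row-mean imputed before projection.  With ``scale_conditions`` each
    condition is additionally scaled to unit variance.
    """
    n_rows, n_cond = len(expr.rows), len(expr.conditions)
    if n_components > min(n_rows, n_cond):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows, conditions)="
            f"{min(n_rows, n_cond)}"
        )
    X = expr.values.copy()
    row_means = np.nanmean(X, axis=1, keepdims=True)
    missing = np.isnan(X)
    if missing.any():
        X[missing] = np.broadcast_to(row_means, X.shape)[missing]
    if scale_conditions:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return ReducedCoordinates(
        rows=list(expr.rows),
        coords=coords,
        explained_variance_fractions=[float(f) for f in pca.explained_variance_ratio_],
    )


def candidate_sets_for_gene(
    gene: str,
    binding: BindingTable,
    coords: ReducedCoordinates,
    kmeans_seed: int = 0,
    n_restarts: int = 10,
    include_full_set_for_pairs: bool = False,
) -> list[CandidateSet]:
    """Propose co-expressed candidate TF sets for one gene.

    k-means (k-means++ init, ``n_restarts`` restarts, fixed seed) is run
    on the reduced coordinates of the gene's binding TFs for each k from
    2 to the number of binding TFs with coordinates; every cluster with
    at least two members becomes a candidate.  Singleton clusters are
    discarded — a lone TF cannot express cooperation.  Two distinct TFs
    always split into singletons at k=2, so 2-TF genes produce no
    candidates unless ``include_full_set_for_pairs`` admits the pair.
    """
    tfs_all = binding.tfs_of(gene)
    if not tfs_all:
        raise KeyError(f"gene {gene!r} has no binding TFs")
    tfs = sorted(t for t in tfs_all if t in coords)
    dropped = tfs_all - set(tfs)
    if dropped:
        warnings.warn(
            f"gene {gene}: {len(dropped)} binding TF(s) lack expression rows "
            "and were dropped before clustering"
        )
    m = len(tfs)
    found: dict[frozenset[str], set[int]] = {}
    if m >= 2:
        X = coords.of(tfs)
        for k in range(2, m + 1):
            n_distinct = len({tuple(row) for row in X})
            if k > n_distinct:
                continue  # k-means cannot place k centres on fewer points
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=n_restarts,
                random_state=kmeans_seed,
            )
            labels = km.fit_predict(X)
            for lab in np.unique(labels):
                members = frozenset(tfs[i] for i in np.flatnonzero(labels == lab))
                if len(members) >= 2:
                    found.setdefault(members, set()).add(k)
    if include_full_set_for_pairs and m == 2:
        found.setdefault(frozenset(tfs), set()).add(2)
    return [
        CandidateSet(gene=gene, tfs=members, k_values=frozenset(ks))
        for members, ks in sorted(found.items(), key=lambda kv: sorted(kv[0]))
    ]


def all_candidate_sets(
    binding: BindingTable,
    coords: ReducedCoordinates,
    seed: int = 0,
    n_restarts: int = 10,
    include_full_set_for_pairs: bool = False,
) -> dict[str, list[CandidateSet]]:
    """Candidate sets for every gene in the binding table (deterministic
    for a fixed seed; genes are processed in sorted order)."""
    out: dict[str, list[CandidateSet]] = {}
    for gene in sorted(binding.genes):
        sets = candidate_sets_for_gene(
            gene,
            binding,
            coords,
            kmeans_seed=seed,
            n_restarts=n_restarts,
            include_full_set_for_pairs=include_full_set_for_pairs,
        )
        if sets:
            out[gene] = sets
    return out
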