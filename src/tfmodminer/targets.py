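"""Module-assisted identification of functional TF binding targets.

Binding signals from ChIP experiments overlap only weakly with knockout
regulation because redundant TFs in the same module back each other up:
deleting one leaves the target's expression unchanged.  A binding pair
(t, g) is therefore called functional when either

* (t, g) itself appears in the knockout data (``knockout_inferred``), or
* t belongs to a confident regulatory module in which (i) some member TF
  has knockout evidence on g and (ii) some OTHER member TF also binds g
  (``pure_module_inferred`` — the redundancy-masked case).

The two labels partition the functional subset of the binding pairs,
and the summary reports their counts and percentages of all binding
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import BindingTable, FunctionalPair, RegulationSet, TFModule


def infer_functional_pairs(
    binding: BindingTable,
    knockout: RegulationSet,
    modules: list[TFModule],
    require_module_gene: bool = False,
) -> set[FunctionalPair]:
    """Label each binding pair using the knockout data and confident modules.

    Knockout overlap takes precedence; module witnesses (the member TF
    with knockout evidence and the second binder) are recorded on
    module-inferred pairs.  With ``require_module_gene`` only modules
    mined for the pair's own gene may act as witnesses (the strict
    reading); by default any confident module containing the TF may.
    """
    by_tf: dict[str, list[tuple[str, TFModule]]] = {}
    for i, mod in enumerate(modules):
        mid = f"M{i:05d}"
        for t in mod.terminals:
            by_tf.setdefault(t, []).append((mid, mod))

    ko_by_gene: dict[str, set[str]] = {}
    for t, g in knockout.pairs:
        ko_by_gene.setdefault(g, set()).add(t)
    binders_by_gene = binding.gene_to_tfs()

    out: set[FunctionalPair] = set()
    for tf, gene in sorted(binding.pairs):
        if (tf, gene) in knockout:
            out.add(FunctionalPair(tf=tf, gene=gene, label="knockout_inferred"))
            continue
        ko_tfs = ko_by_gene.get(gene, set())
        binders = binders_by_gene.get(gene, frozenset())
        for mid, mod in sorted(by_tf.get(tf, []), key=lambda x: x[0]):
            if require_module_gene and mod.gene != gene:
                continue
            witness_ko = sorted(mod.terminals & ko_tfs)
            witness_bind = sorted(t for t in mod.terminals & binders if t != tf)
            if witness_ko and witness_bind:
                out.add(
                    FunctionalPair(
                        tf=tf,
                        gene=gene,
                        label="pure_module_inferred",
                        witness_module=mid,
                        witness_knockout_tf=witness_ko[0],
                        witness_binder_tf=witness_bind[0],
                    )
                )
                break
    return out


@dataclass
class FunctionalSummary:
    """Counts and one-decimal percentages over all binding pairs."""

    total_binding_pairs: int
    knockout_inferred: int
    pure_module_inferred: int
    tfs_with_functional_target: int

    @property
    def functional_total(self) -> int:
        return self.knockout_inferred + self.pure_module_inferred

    @property
    def knockout_pct(self) -> float:
        return round(100.0 * self.knockout_inferred / self.total_binding_pairs, 1)

    @property
    def pure_module_pct(self) -> float:
        return round(100.0 * self.pure_module_inferred / self.total_binding_pairs, 1)

    @property
    def functional_pct(self) -> float:
        return round(100.0 * self.functional_total / self.total_binding_pairs, 1)


def functional_fraction_summary(
    pairs: set[FunctionalPair], binding: BindingTable
) -> FunctionalSummary:
    """Summarise the functional-pair accounting for a binding table.

    The two labels are disjoint by construction, so the union count is
    their sum; percentages are relative to ALL thresholded binding pairs
    and reported to one decimal place.
    """
    if len(binding) == 0:
        raise ValueError("binding table is empty")
    ko = sum(1 for p in pairs if p.label == "knockout_inferred")
    pm = sum(1 for p in pairs if p.label == "pure_module_inferred")
    if ko + pm != len({(p.tf, p.gene) for p in pairs}):
        raise AssertionError("functional labels do not partition the pair set")
    return FunctionalSummary(
        total_binding_pairs=len(binding),
        knockout_inferred=ko,
        pure_module_inferred=pm,
        tfs_with_functional_target=len({p.tf for p in pairs}),
    )


def summary_from_counts(
    total: int, knockout_inferred: int, pure_module_inferred: int
) -> FunctionalSummary:
    """Accounting summary straight from printed counts (no pair objects)."""
    if total <= 0:
        raise ValueError("total binding pairs must be positive")
    return FunctionalSummary(
        total_binding_pairs=total,
        knockout_inferred=knockout_inferred,
        pure_module_inferred=pure_module_inferred,
        tfs_with_functional_target=0,
    )


def write_functional_pairs(pairs: set[FunctionalPair], path: str) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write(
            "tf\tgene\tlabel\twitness_module\twitness_knockout_tf\twitness_binder_tf\n"
        )
        for p in sorted(pairs, key=lambda p: (p.tf, p.gene)):
            fh.write(
                f"{p.tf}\t{p.gene}\t{p.label}\t{p.witness_module or ''}\t"
                f"{p.witness_knockout_tf or ''}\t{p.witness_binder_tf or ''}\n"
            )
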