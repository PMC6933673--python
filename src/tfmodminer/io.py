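"""Readers, writers and shared domain containers.

All tabular inputs are plain tab-separated text:

* binding table      -- ``tf <TAB> gene <TAB> p_value`` with a header row
* confidence network -- ``protein_a <TAB> protein_b <TAB> confidence``
* expression matrix  -- row identifiers in column 1, one column per condition
* annotations        -- two-column ``entity <TAB> term`` or a GAF 2.x subset
* knockout pairs     -- ``tf <TAB> gene``

Identifiers are opaque, case-sensitive strings; no gene-name normalisation
is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A malformed input row or an unsupported format label."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingTable:
    """Thresholded TF -> gene binding pairs with their binding p-values.

    ``pairs`` maps ``(tf, gene)`` to the binding p-value; every retained
    pair satisfies ``p <= alpha`` (the threshold is inclusive).
    """

    pairs: dict[tuple[str, str], float]
    alpha: float

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(t for t, _ in self.pairs)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)

    def tfs_of(self, gene: str) -> frozenset[str]:
        return frozenset(t for (t, g) in self.pairs if g == gene)

    def genes_of(self, tf: str) -> frozenset[str]:
        return frozenset(g for (t, g) in self.pairs if t == tf)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def gene_to_tfs(self) -> dict[str, frozenset[str]]:
        """One pass grouping of binding TFs per gene (avoids O(genes*pairs))."""
        out: dict[str, set[str]] = {}
        for tf, gene in self.pairs:
            out.setdefault(gene, set()).add(tf)
        return {g: frozenset(s) for g, s in out.items()}


@dataclass
class ExpressionMatrix:
    """Gene/TF by condition log-ratio expression with a missing-value mask."""

    rows: list[str]
    conditions: list[str]
    values: np.ndarray  # float matrix, NaN where missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.conditions)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.rows)} rows x {len(self.conditions)} conditions"
            )
        if len(set(self.rows)) != len(self.rows):
            raise ValueError("duplicate row identifiers")
        self._index = {r: i for i, r in enumerate(self.rows)}

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def __contains__(self, row: str) -> bool:
        return row in self._index

    def row(self, identifier: str) -> np.ndarray:
        return self.values[self._index[identifier]]


class ConfidenceNetwork:
    """Undirected protein-interaction graph with per-edge confidence.

    The edge weight used by the Steiner machinery is ``1 - confidence``,
    so the most trusted interactions are the cheapest to include.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()) -> None:
        self._conf: dict[tuple[str, str], float] = {}
        self._adj: dict[str, set[str]] = {}
        for a, b, c in edges:
            self.add_edge(a, b, c)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_edge(self, a: str, b: str, confidence: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if not 0.0 < confidence <= 1.0:
            raise ValueError(f"confidence {confidence} outside (0, 1] for edge ({a}, {b})")
        self._conf[self._key(a, b)] = float(confidence)
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._adj)

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def neighbors(self, node: str) -> frozenset[str]:
        return frozenset(self._adj.get(node, ()))

    def has_edge(self, a: str, b: str) -> bool:
        return self._key(a, b) in self._conf

    def confidence(self, a: str, b: str) -> float:
        return self._conf[self._key(a, b)]

    def weight(self, a: str, b: str) -> float:
        return 1.0 - self._conf[self._key(a, b)]

    def edges(self) -> list[tuple[str, str, float]]:
        """All edges as (a, b, confidence), endpoint-sorted then lexicographic."""
        return [(a, b, c) for (a, b), c in sorted(self._conf.items())]

    def confidences(self) -> np.ndarray:
        return np.array([c for _, c in sorted(self._conf.items())])

    @property
    def n_edges(self) -> int:
        return len(self._conf)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ConfidenceNetwork) and self._conf == other._conf


@dataclass(frozen=True)
class AnnotationMap:
    """Entity -> set of annotation terms (e.g. GO ids), optionally per aspect."""

    mapping: Mapping[str, frozenset[str]]
    aspects: Mapping[str, Mapping[str, frozenset[str]]] | None = None

    def terms(self, entity: str, aspect: str | None = None) -> frozenset[str]:
        if aspect is not None:
            if self.aspects is None or aspect not in self.aspects:
                return frozenset()
            return self.aspects[aspect].get(entity, frozenset())
        return self.mapping.get(entity, frozenset())

    @property
    def entities(self) -> frozenset[str]:
        return frozenset(self.mapping)

    def all_terms(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.mapping.values():
            out |= ts
        return frozenset(out)


@dataclass(frozen=True)
class RegulationSet:
    """Deduplicated TF -> gene knockout-regulation pairs."""

    pairs: frozenset[tuple[str, str]]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def tfs_regulating(self, gene: str) -> frozenset[str]:
        return frozenset(t for (t, g) in self.pairs if g == gene)


@dataclass
class CandidateSet:
    """Co-expressed candidate TF subset proposed for one gene (stage 1)."""

    gene: str
    tfs: frozenset[str]
    k_values: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.tfs) < 2:
            raise ValueError("a candidate set needs at least two TFs")


@dataclass
class TFModule:
    """A mined regulatory module: terminal TFs plus recruited mediators.

    The subgraph is a tree; ``cost`` is the sum of edge weights
    (``1 - confidence``).  ``p_value``/``q_value`` are filled in by the
    noise-reduction stage.
    """

    gene: str
    terminals: frozenset[str]
    mediators: frozenset[str]
    edges: frozenset[tuple[str, str, float]]
    cost: float
    p_value: float | None = None
    q_value: float | None = None

    @property
    def nodes(self) -> frozenset[str]:
        return self.terminals | self.mediators

    def edge_confidences(self) -> np.ndarray:
        return np.array(sorted(c for _, _, c in self.edges))


@dataclass(frozen=True)
class FunctionalPair:
    """A binding pair explained by knockout evidence or by a confident module."""

    tf: str
    gene: str
    label: str  # "knockout_inferred" | "pure_module_inferred"
    witness_module: str | None = None
    witness_knockout_tf: str | None = None
    witness_binder_tf: str | None = None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _split_line(line: str, n_fields: int, path: str, lineno: int) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < n_fields or any(not p for p in parts[:n_fields]):
        raise FormatError(f"{path}:{lineno}: expected {n_fields} tab-separated fields")
    return parts


def read_binding_table(path: str | Path, alpha: float = 0.05) -> BindingTable:
    """Read a ``tf<TAB>gene<TAB>p_value`` table and keep rows with ``p <= alpha``.

    Duplicate (tf, gene) rows keep the smallest p-value (a warning is
    emitted); the inclusive threshold and the retained alpha are recorded
    on the returned table.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    path = Path(path)
    pairs: dict[tuple[str, str], float] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 or not line.strip():
                continue  # header
            tf, gene, p_str = _split_line(line, 3, str(path), lineno)[:3]
            try:
                p = float(p_str)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric p-value {p_str!r}") from exc
            if not 0.0 <= p <= 1.0:
                raise FormatError(f"{path}:{lineno}: p-value {p} outside [0, 1]")
            if p > alpha:
                continue
            key = (tf, gene)
            if key in pairs:
                warnings.warn(f"duplicate binding pair {key}; keeping the smaller p-value")
                pairs[key] = min(pairs[key], p)
            else:
                pairs[key] = p
    return BindingTable(pairs=pairs, alpha=alpha)


def write_binding_table(table: BindingTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("tf\tgene\tp_value\n")
        for (tf, gene), p in sorted(table.pairs.items()):
            fh.write(f"{tf}\t{gene}\t{p:.17g}\n")


def read_confidence_network(path: str | Path, scale_1000: bool = False) -> ConfidenceNetwork:
    """Read a ``protein_a<TAB>protein_b<TAB>confidence`` edge list.

    STRING-style integer scores on a 0-1000 scale are divided by 1000 when
    ``scale_1000`` is set.  Duplicate listings of the same undirected edge
    collapse to the maximum confidence; self-loops are dropped with a
    warning.
    """
    path = Path(path)
    net = ConfidenceNetwork()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 or not line.strip():
                continue
            a, b, c_str = _split_line(line, 3, str(path), lineno)[:3]
            try:
                c = float(c_str)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric confidence {c_str!r}") from exc
            if scale_1000:
                c /= 1000.0
            if a == b:
                warnings.warn(f"{path}:{lineno}: self-loop on {a!r} skipped")
                continue
            if not 0.0 < c <= 1.0:
                raise FormatError(f"{path}:{lineno}: confidence {c} outside (0, 1]")
            if net.has_edge(a, b):
                net.add_edge(a, b, max(c, net.confidence(a, b)))
            else:
                net.add_edge(a, b, c)
    return net


def write_confidence_network(net: ConfidenceNetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein_a\tprotein_b\tconfidence\n")
        for a, b, c in net.edges():
            fh.write(f"{a}\t{b}\t{c:.17g}\n")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV matrix: row identifiers in column 1, conditions across.

    Empty cells become masked (NaN) values; rows that are entirely missing
    are rejected, as are duplicated row identifiers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row identifier {dup!r}")
    values = df.to_numpy(dtype=float)
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        bad = df.index[all_missing][0]
        raise FormatError(f"{path}: row {bad!r} has no observed values")
    return ExpressionMatrix(
        rows=[str(r) for r in df.index],
        conditions=[str(c) for c in df.columns],
        values=values,
    )


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.rows, columns=expr.conditions)
    df.to_csv(path, sep="\t", index_label="id")


def read_annotations(path: str | Path, format: str = "two_column") -> AnnotationMap:
    """Read entity -> term annotations.

    ``two_column``: ``entity<TAB>term`` rows.  ``gaf_subset``: GAF 2.x
    lines where column 2 is the object id and column 5 the GO id; comment
    lines starting with ``!`` are skipped.  Duplicate (entity, term) rows
    collapse.
    """
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if format == "two_column":
                entity, term = _split_line(line, 2, str(path), lineno)[:2]
            elif format == "gaf_subset":
                if line.startswith("!"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    raise FormatError(f"{path}:{lineno}: GAF line with fewer than 5 columns")
                entity, term = parts[1], parts[4]
            else:
                raise FormatError(f"unknown annotation format {format!r}")
            mapping.setdefault(entity, set()).add(term)
    return AnnotationMap(mapping={e: frozenset(t) for e, t in mapping.items()})


def read_regulation_pairs(path: str | Path) -> RegulationSet:
    """Read ``tf<TAB>gene`` knockout-regulation pairs, deduplicated."""
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if lineno == 1 and line.rstrip("\n").split("\t")[:2] == ["tf", "gene"]:
                continue
            tf, gene = _split_line(line, 2, str(path), lineno)[:2]
            pairs.add((tf, gene))
    return RegulationSet(pairs=frozenset(pairs))


def write_regulation_pairs(reg: RegulationSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("tf\tgene\n")
        for tf, gene in sorted(reg.pairs):
            fh.write(f"{tf}\t{gene}\n")


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for entity in sorted(ann.mapping):
            for term in sorted(ann.mapping[entity]):
                fh.write(f"{entity}\t{term}\n")


# ---------------------------------------------------------------------------
# module table
# ---------------------------------------------------------------------------

_MODULE_COLUMNS = [
    "module_id",
    "gene",
    "member_tfs",
    "mediator_proteins",
    "edges",
    "cost",
    "p_value",
    "q_value",
]


def write_modules(modules: Iterable[TFModule], path: str | Path) -> None:
    """Write modules as TSV; edges serialise as ``a;b;confidence`` triples
    joined with commas, TF/mediator lists comma-joined."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(_MODULE_COLUMNS) + "\n")
        for i, m in enumerate(modules):
            edges = ",".join(
                f"{a};{b};{c:.17g}" for a, b, c in sorted(m.edges)
            )
            fh.write(
                "\t".join(
                    [
                        f"M{i:05d}",
                        m.gene,
                        ",".join(sorted(m.terminals)),
                        ",".join(sorted(m.mediators)),
                        edges,
                        f"{m.cost:.17g}",
                        "" if m.p_value is None else f"{m.p_value:.17g}",
                        "" if m.q_value is None else f"{m.q_value:.17g}",
                    ]
                )
                + "\n"
            )


def read_modules(path: str | Path) -> list[TFModule]:
    path = Path(path)
    modules: list[TFModule] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MODULE_COLUMNS:
            raise FormatError(f"{path}: unexpected module table header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_MODULE_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(_MODULE_COLUMNS)} fields")
            _, gene, tfs, meds, edges_str, cost, p, q = parts
            edges: set[tuple[str, str, float]] = set()
            if edges_str:
                for triple in edges_str.split(","):
                    a, b, c = triple.split(";")
                    edges.add((a, b, float(c)))
            modules.append(
                TFModule(
                    gene=gene,
                    terminals=frozenset(tfs.split(",")) if tfs else frozenset(),
                    mediators=frozenset(meds.split(",")) if meds else frozenset(),
                    edges=frozenset(edges),
                    cost=float(cost),
                    p_value=float(p) if p else None,
                    q_value=float(q) if q else None,
                )
            )
    return modules
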