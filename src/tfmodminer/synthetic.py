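"""Synthetic benchmark datasets with planted TF regulatory modules.

The generator emits the five inputs the mining pipeline consumes —
binding table, expression matrix, confidence-weighted interaction
network, annotations and knockout pairs — in a form that is internally
consistent with a set of planted modules:

* each planted module is a group of TFs sharing one latent expression
  factor (so they co-cluster in stage 1),
* the module's TFs are wired to a designated mediator hub at a high,
  uniform confidence (so stage 2 recovers a star through the hub and
  stage 3 sees confidences well above the background),
* every module TF binds every one of the module's target genes, and
* under ``masking`` only ONE TF per module carries knockout evidence on
  the shared targets — the redundancy-masking effect seen in real
  knockout screens, where backup TFs hide each other's deletion
  phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    AnnotationMap,
    BindingTable,
    ConfidenceNetwork,
    ExpressionMatrix,
    RegulationSet,
    TFModule,
)


@dataclass(frozen=True)
class PlantedModule:
    """Ground truth for one planted module."""

    tfs: frozenset[str]
    mediators: frozenset[str]
    targets: frozenset[str]
    knockout_tf: str  # the single TF with knockout evidence under masking


@dataclass
class SyntheticConfig:
    """Knobs of the generator.

    Defaults describe a small but non-trivial study: a few dozen TFs over
    enough conditions for co-expression to be detectable, a sparse
    background interaction network whose confidences sit clearly below
    the planted-module wiring, and redundancy masking switched on.
    """

    n_tfs: int = 30
    n_genes: int = 60
    n_mediators: int = 10
    n_conditions: int = 60
    n_planted_modules: int = 2
    module_size: int = 3
    targets_per_module: int = 5
    background_edge_prob: float = 0.05
    planted_confidence: float = 0.97
    background_confidence_range: tuple[float, float] = (0.2, 0.6)
    coexpression_strength: float = 3.0
    noise_sd: float = 1.0
    background_binding_prob: float = 0.1
    binding_alpha: float = 0.05
    masking: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.module_size < 2:
            raise ValueError("module_size must be at least 2")
        for name in (
            "n_tfs",
            "n_genes",
            "n_mediators",
            "n_conditions",
            "module_size",
            "targets_per_module",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_modules < 0:
            raise ValueError("n_planted_modules must be non-negative")
        lo, hi = self.background_confidence_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("background_confidence_range must satisfy 0 < lo <= hi < 1")
        if not hi < self.planted_confidence <= 1.0:
            raise ValueError(
                "planted_confidence must exceed the background confidence range"
            )
        if self.n_planted_modules * self.module_size > self.n_tfs:
            raise ValueError("not enough TFs for the requested planted modules")
        if self.n_planted_modules * self.targets_per_module > self.n_genes:
            raise ValueError("not enough genes for the requested planted targets")
        if self.n_planted_modules > self.n_mediators:
            raise ValueError("each planted module needs its own mediator hub")


@dataclass
class SyntheticBundle:
    """The five pipeline inputs plus the planted ground truth."""

    binding: BindingTable
    expression: ExpressionMatrix
    network: ConfidenceNetwork
    annotations: AnnotationMap
    knockout: RegulationSet
    truth: list[PlantedModule]
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore[assignment]


def generate_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Build one reproducible bundle; identical seeds give identical bundles.

    One ``numpy`` generator seeded from ``config.seed`` drives every draw,
    consumed in a fixed order: expression factors/noise, background
    binding, background network edges, background annotations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    tfs = [f"TF{i:03d}" for i in range(config.n_tfs)]
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    mediators = [f"MED{i:02d}" for i in range(config.n_mediators)]

    # --- plant module memberships (deterministic block assignment) -------
    truth: list[PlantedModule] = []
    for m in range(config.n_planted_modules):
        mod_tfs = tfs[m * config.module_size : (m + 1) * config.module_size]
        mod_targets = genes[
            m * config.targets_per_module : (m + 1) * config.targets_per_module
        ]
        truth.append(
            PlantedModule(
                tfs=frozenset(mod_tfs),
                mediators=frozenset({mediators[m]}),
                targets=frozenset(mod_targets),
                knockout_tf=mod_tfs[0],
            )
        )

    # --- expression: shared latent factor per module + Gaussian noise ----
    n_rows = len(tfs) + len(genes)
    values = rng.normal(0.0, config.noise_sd, size=(n_rows, config.n_conditions))
    for planted in truth:
        factor = rng.normal(0.0, 1.0, size=config.n_conditions)
        for tf in sorted(planted.tfs):
            values[tfs.index(tf)] += config.coexpression_strength * factor
    expression = ExpressionMatrix(
        rows=tfs + genes,
        conditions=[f"cond{j:04d}" for j in range(config.n_conditions)],
        values=values,
    )

    # --- binding: planted TFs bind planted targets, plus sparse noise ----
    pairs: dict[tuple[str, str], float] = {}
    for planted in truth:
        for tf in sorted(planted.tfs):
            for g in sorted(planted.targets):
                pairs[(tf, g)] = float(rng.uniform(0.0, config.binding_alpha))
    for tf in tfs:
        for g in genes:
            if (tf, g) not in pairs and rng.uniform() < config.background_binding_prob:
                pairs[(tf, g)] = float(rng.uniform(0.0, config.binding_alpha))
    binding = BindingTable(pairs=pairs, alpha=config.binding_alpha)

    # --- network: star through each module's hub + ER background ---------
    network = ConfidenceNetwork()
    for planted in truth:
        hub = min(planted.mediators)
        for tf in sorted(planted.tfs):
            network.add_edge(tf, hub, config.planted_confidence)
    lo, hi = config.background_confidence_range
    all_nodes = tfs + mediators
    for i, a in enumerate(all_nodes):
        for b in all_nodes[i + 1 :]:
            if network.has_edge(a, b):
                continue
            if rng.uniform() < config.background_edge_prob:
                network.add_edge(a, b, float(rng.uniform(lo, hi)))
    # keep isolated nodes queryable: attach any isolated TF/mediator to a
    # random partner at a background confidence so Steiner search can run
    for node in all_nodes:
        if node not in network:
            partner = all_nodes[int(rng.integers(len(all_nodes)))]
            while partner == node:
                partner = all_nodes[int(rng.integers(len(all_nodes)))]
            network.add_edge(node, partner, float(rng.uniform(lo, hi)))

    # --- annotations: shared term block per module + private terms -------
    mapping: dict[str, set[str]] = {t: set() for t in tfs}
    for m, planted in enumerate(truth):
        shared = {f"GO:SH{m:02d}{j}" for j in range(3)}
        for tf in sorted(planted.tfs):
            mapping[tf] |= shared
            mapping[tf].add(f"GO:PRIV:{tf}")
        for g in sorted(planted.targets):
            mapping.setdefault(g, set()).update({f"GO:TGT{m:02d}{j}" for j in range(2)})
    for tf in tfs:
        if not mapping[tf]:
            n_private = int(rng.integers(1, 4))
            mapping[tf] = {f"GO:BG{int(rng.integers(100)):03d}" for _ in range(n_private)}
            mapping[tf].add(f"GO:PRIV:{tf}")
    annotations = AnnotationMap(mapping={e: frozenset(t) for e, t in mapping.items()})

    # --- knockout: masked (one TF per module) or full --------------------
    ko: set[tuple[str, str]] = set()
    for planted in truth:
        sources = [planted.knockout_tf] if config.masking else sorted(planted.tfs)
        for tf in sources:
            for g in sorted(planted.targets):
                ko.add((tf, g))
    knockout = RegulationSet(pairs=frozenset(ko))

    return SyntheticBundle(
        binding=binding,
        expression=expression,
        network=network,
        annotations=annotations,
        knockout=knockout,
        truth=truth,
        config=config,
    )


def recovery_score(predicted: list[TFModule], truth: list[PlantedModule]) -> float:
    """Mean, over planted modules, of the best Jaccard index between the
    planted TF set and any predicted module's terminal set.

    Returns 0.0 when nothing was predicted; 1.0 on exact recovery of every
    planted module.
    """
    if not predicted:
        return 0.0
    if not truth:
        return 1.0
    scores = []
    for planted in truth:
        best = 0.0
        for mod in predicted:
            inter = len(planted.tfs & mod.terminals)
            union = len(planted.tfs | mod.terminals)
            if union:
                best = max(best, inter / union)
        scores.append(best)
    return float(np.mean(scores))
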