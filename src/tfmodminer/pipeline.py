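"""End-to-end orchestration of the three mining stages plus downstream
target inference, with deterministic seeding and per-stage counts.

The stages compose as

    candidate search  ->  module mining  ->  noise reduction
          (PCA + k-means)      (Steiner approx.)     (Mann-Whitney + BH)

followed by functional-target labelling against the knockout data.  One
global seed fans out to stage-specific seeds by fixed offsets so each
stage is independently re-runnable.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import candidates as cand_mod
from . import io, mining, noise, targets
from .io import BindingTable, CandidateSet, ConfidenceNetwork, ExpressionMatrix, RegulationSet, TFModule
from .noise import ConfidenceTestResult

log = logging.getLogger(__name__)

# fixed fan-out offsets so stages are independently reproducible
_KMEANS_SEED_OFFSET = 1


@dataclass
class PipelineConfig:
    binding_path: str
    expression_path: str
    network_path: str
    knockout_path: str | None = None
    annotations_path: str | None = None
    output_dir: str = "tfmodminer_out"
    alpha_binding: float = 0.05
    alpha_module: float = 0.05
    alpha_enrichment: float = 0.05
    pca_components: int = 3
    seed: int = 0
    kmeans_restarts: int = 10
    network_scale_1000: bool = False
    global_fdr: bool = False
    include_full_set_for_pairs: bool = False
    require_module_gene: bool = False

    def validate(self) -> None:
        for name in ("alpha_binding", "alpha_module", "alpha_enrichment"):
            a = getattr(self, name)
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{name}={a} outside (0, 1]")
        required = [self.binding_path, self.expression_path, self.network_path]
        optional = [self.knockout_path, self.annotations_path]
        for p in required + [p for p in optional if p]:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file missing: {p}")


@dataclass
class RunReport:
    n_binding_pairs: int = 0
    n_candidate_sets: int = 0
    n_mined_modules: int = 0
    n_confident_modules: int = 0
    n_functional_pairs: int = 0
    outputs: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)


def run_stages(
    binding: BindingTable,
    expression: ExpressionMatrix,
    network: ConfidenceNetwork,
    seed: int = 0,
    pca_components: int = 3,
    kmeans_restarts: int = 10,
    alpha_module: float = 0.05,
    global_fdr: bool = False,
    include_full_set_for_pairs: bool = False,
) -> tuple[dict[str, list[CandidateSet]], list[TFModule], list[TFModule], list[ConfidenceTestResult]]:
    """Run the three mining stages on in-memory inputs.

    Returns ``(candidate_sets, mined_modules, confident_modules,
    confidence_test_results)``.
    """
    coords = cand_mod.reduce_expression(expression, n_components=pca_components)
    candidate_sets = cand_mod.all_candidate_sets(
        binding,
        coords,
        seed=seed + _KMEANS_SEED_OFFSET,
        n_restarts=kmeans_restarts,
        include_full_set_for_pairs=include_full_set_for_pairs,
    )
    mined = mining.mine_all_modules(network, candidate_sets)
    confident, results = noise.filter_modules(
        mined, network, alpha=alpha_module, global_fdr=global_fdr
    )
    return candidate_sets, mined, confident, results


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Load inputs, run all stages, write stage outputs, return the report.

    Every stage logs its input/output counts; missing inputs abort before
    stage 1 starts.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    t0 = time.perf_counter()
    binding = io.read_binding_table(config.binding_path, alpha=config.alpha_binding)
    expression = io.read_expression_matrix(config.expression_path)
    network = io.read_confidence_network(
        config.network_path, scale_1000=config.network_scale_1000
    )
    knockout = (
        io.read_regulation_pairs(config.knockout_path)
        if config.knockout_path
        else RegulationSet(pairs=frozenset())
    )
    report.n_binding_pairs = len(binding)
    report.timings["load"] = time.perf_counter() - t0
    log.info("loaded %d binding pairs, %d network edges", len(binding), network.n_edges)

    t0 = time.perf_counter()
    candidate_sets, mined, confident, results = run_stages(
        binding,
        expression,
        network,
        seed=config.seed,
        pca_components=config.pca_components,
        kmeans_restarts=config.kmeans_restarts,
        alpha_module=config.alpha_module,
        global_fdr=config.global_fdr,
        include_full_set_for_pairs=config.include_full_set_for_pairs,
    )
    report.n_candidate_sets = sum(len(v) for v in candidate_sets.values())
    report.n_mined_modules = len(mined)
    report.n_confident_modules = len(confident)
    report.timings["mine"] = time.perf_counter() - t0
    log.info(
        "stage counts: %d candidate sets -> %d mined -> %d confident",
        report.n_candidate_sets,
        report.n_mined_modules,
        report.n_confident_modules,
    )

    cand_path = outdir / "candidates.tsv"
    with cand_path.open("w") as fh:
        fh.write("gene\ttfs\tk_values\n")
        for gene in sorted(candidate_sets):
            for cs in candidate_sets[gene]:
                fh.write(
                    f"{gene}\t{','.join(sorted(cs.tfs))}\t"
                    f"{','.join(str(k) for k in sorted(cs.k_values))}\n"
                )
    io.write_modules(mined, outdir / "modules_mined.tsv")
    io.write_modules(confident, outdir / "modules_confident.tsv")
    report.outputs["candidates"] = str(cand_path)
    report.outputs["modules_mined"] = str(outdir / "modules_mined.tsv")
    report.outputs["modules_confident"] = str(outdir / "modules_confident.tsv")

    if len(knockout):
        t0 = time.perf_counter()
        pairs = targets.infer_functional_pairs(
            binding, knockout, confident, require_module_gene=config.require_module_gene
        )
        report.n_functional_pairs = len(pairs)
        fp_path = outdir / "functional_pairs.tsv"
        targets.write_functional_pairs(pairs, str(fp_path))
        report.outputs["functional_pairs"] = str(fp_path)
        report.timings["targets"] = time.perf_counter() - t0
        if pairs:
            s = targets.functional_fraction_summary(pairs, binding)
            log.info(
                "functional pairs: %d knockout-inferred (%.1f%%), "
                "%d pure module-inferred (%.1f%%), union %.1f%%",
                s.knockout_inferred,
                s.knockout_pct,
                s.pure_module_inferred,
                s.pure_module_pct,
                s.functional_pct,
            )
    return report
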