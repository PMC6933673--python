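# Methods

## The problem

Genome-wide ChIP binding data for transcription factors (TFs) overlap
surprisingly little with TF-knockout regulation data: most binding
signals show no expression change when the bound TF is deleted.  A large
part of this gap is attributed to functional redundancy — several TFs
cooperating in a regulatory module back each other up, so deleting one
leaves the target unaffected.  `tfmodminer` mines such TF regulatory
modules from three data sources (TF→gene binding p-values, a gene ×
condition expression compendium, and a confidence-weighted
protein-interaction network) and uses them to (a) quantify functional
redundancy and (b) re-identify binding pairs that knockout screens miss.

## The mining algorithm

**Stage 1 — candidate search.**  All expression rows are projected onto
the top three principal components (conditions are mean-centred; rows
with missing values are row-mean imputed; no per-condition rescaling by
default, exposed as a flag).  For each gene, k-means (k-means++, 10
restarts, fixed seed) is run on the reduced coordinates of its binding
TFs for every k from 2 to the number of binding TFs.  Every cluster with
≥ 2 members becomes a candidate TF set; identical sets from different k
are merged and singletons are discarded (a lone TF cannot express
cooperation).  Consequences worth knowing: a gene whose binding TFs are
*all* co-expressed never yields its full TF set (k starts at 2, so the
tightest cluster is split); the full set emerges as soon as the gene also
binds at least one expression-distant TF, which is the typical situation
when genes bind several TFs.  Genes with exactly two binding TFs produce
no candidates under the literal enumeration (k-means on two distinct
points yields singletons); `include_full_set_for_pairs` optionally admits
the pair.

**Stage 2 — module mining.**  The interaction network is weighted by
1 − confidence, so trusted edges are cheap.  For each candidate set the
minimal-cost connected subgraph containing all candidate TFs is the
(NP-hard) Steiner tree problem; we use the Kou–Markowsky–Berman
2-approximation: metric closure over the terminals → MST of the closure
→ expansion of MST edges into their shortest paths → MST of the expanded
subgraph → repeated pruning of non-terminal leaves.  The final two steps
shrink the number of participating proteins, matching the biological
preference for few participating proteins.  Non-terminal nodes retained
in the tree are the module's mediator proteins.  All ties in Dijkstra
and Kruskal break lexicographically on node identifiers, making results
identical across runs and platforms.  Candidate sets with unreachable
terminals are skipped (not silently shrunk — that would change the
hypothesis being tested).

**Stage 3 — noise reduction.**  A genuine module should use interactions
of higher-than-typical confidence, so each module's edge confidences are
compared against the confidences of *all* network edges (including its
own — at realistic network sizes the overlap is negligible and excluding
them would need an arbitrary rule) with a one-sided (greater)
Mann-Whitney U test: exact null when the smaller sample has ≤ 8
observations and no ties, normal approximation with tie correction
otherwise.  P-values are Benjamini–Hochberg adjusted within each gene's
module group (a `global_fdr` flag corrects across all modules instead)
and modules with q ≤ 0.05 are kept.  The BH procedure is the assumed
multiple-testing correction; the named alternatives would be stricter.

## Redundancy scoring and functional targets

The functional redundancy score of TF *t* is the maximum Dice
coefficient between its annotation-term set and that of any *other* TF
in the universe (the maximum over all TFs including *t* would be
identically 1): FRS(t) = max_{q≠t} 2|F_t∩F_q| / (|F_t|+|F_q|) ∈ [0, 1].
Term sets are direct annotations, pooled across ontology aspects by
default; per-aspect scoring and ancestor propagation are options.
Module-member vs non-member TFs are compared with a one-sided Welch
t-test (safer than the pooled-variance form when group variances
differ).  Module coherence is the mean squared Pearson correlation over
all terminal pairs, on raw expression rows, pairwise-complete over
missing values.

A binding pair (t, g) is a **functional target** when (t, g) is itself a
knockout pair (knockout-inferred), or when t sits in a confident module
where (i) some member TF has knockout evidence on g and (ii) some member
TF other than t also binds g (pure module-inferred).  The two labels
partition the functional set.  Modules are matched by TF membership, not
by the gene they were mined for (the permissive reading;
`require_module_gene` implements the strict one).  Witness TFs and the
witness module are recorded so every label can be re-verified by brute
force.  Percentages are reported to one decimal place over all
thresholded binding pairs.

## Significance evaluation

*GO enrichment*: per-term upper-tail hypergeometric p-values over the
term universe annotating ≥ 1 target gene, BH-corrected; summaries are
the log enrichment score (Σ −log10 p over significant terms, base 10)
and the odds-ratio score (Σ Haldane–Anscombe ½-corrected odds ratios, so
zero cells stay finite).  *Interaction prevalence*: targets with a
physical interaction to another target form the core; non-targets
adjacent to the core are the neighbors; core ∪ neighbors is the complex;
the p-value is the upper-tail hypergeometric probability that a random
gene set of the target set's size captures ≥ |core| complex members.
The sampling model for this test is a design choice (the informal
"proportion of the core to the complex vs complex to genome" statement
does not pin one down); the raw (core, complex, genome) counts are
exposed so alternative tests can be applied.  *Expression coherence*:
within-set pairwise r² distributions compared per condition dataset with
one-tailed rank-sum tests in both directions, BH across conditions; a
condition is won by the set whose corrected test is significant while
the mirror test is not.

## Synthetic data

The generator plants modules with known structure: each planted module
is a disjoint block of TFs sharing one latent expression factor
(expression = loading × factor + Gaussian noise; background TFs are
pure noise), wired as a star through a designated mediator hub at a
fixed high confidence, binding a disjoint block of target genes.  The
background network is Erdős–Rényi with confidences drawn well below the
planted level; annotations give each module's TFs a shared term block
plus private terms; and under `masking` exactly one TF per module
carries knockout evidence on the shared targets — the redundancy-masking
effect the miner is supposed to see through.

Default sizes (30 TFs, 60 genes, 10 mediators, 60 conditions, 2 planted
modules of 3 TFs × 5 targets) are the smallest configuration at which
every stage operates in its intended regime: the Mann-Whitney stage
needs a background edge population of dozens of edges before a 2–4-edge
module can reach p < 0.05 at all, and genes must occasionally bind
background TFs (probability 0.1 per TF-gene pair) so that a fully
co-expressed candidate set can appear as a k-means cluster — real genes
bind many TFs, so this mirrors practice.  The coexpression loading (3.0)
is three times the noise standard deviation (1.0), a clearly detectable
but not degenerate signal.  One `numpy` generator seeded per bundle
drives every draw in fixed order, so bundles are bit-identical across
runs.

What the generator does **not** emulate: overlapping module memberships,
scale-free network topology, condition-dependent regulation, correlated
noise across conditions, annotation incompleteness, and genome-scale
sizes.  Passing the recovery tests therefore shows the pipeline is
correct and calibrated under its own model assumptions, not that it will
reach any particular accuracy on real compendia.

## Numerical choices and degenerate inputs

Binding thresholds are inclusive (p ≤ α).  Duplicate binding rows keep
the minimum p; duplicate network edges keep the maximum confidence (both
retain evidence, both warn).  Self-loops are dropped with a warning.
Equal-distance shortest paths and equal-weight MST edges resolve
lexicographically.  Modules with zero edges get confidence p = 1 (a
single node cannot show confidence support).  Correlations over
pairwise-complete observations with fewer than two shared conditions, or
against a constant profile, are excluded from coherence means.  BH
q-values are clamped to be ≥ their p-value.  Random-graph and k-means
seeds are explicit arguments everywhere; the pipeline fans a single seed
out to stages by fixed offsets.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on generated data:
200 random graphs of ≤ 10 nodes for the Steiner 2-approximation bound
(brute force over all node supersets as the oracle), 1000 fuzzed
annotation catalogs for the FRS bounds, 1000 random edge-subsample
modules against a 200-edge network for null calibration, exact-test
oracles up to population 60 (hypergeometric) and combined sample 12
(Mann-Whitney), and 10 synthetic bundles at the default configuration
for end-to-end recovery.

## Known limitations

The candidate stage recomputes k-means for every gene independently;
genes sharing a binding TF set could share the work.  The metric closure
is computed lazily per candidate set, which repeats Dijkstra runs for
TFs appearing in many candidate sets.  The Steiner construction
guarantees a 2-approximation of cost but not minimality of mediator
count.  The prevalence test's null model treats the complex as fixed
while resampling targets, which is one of several defensible readings.
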