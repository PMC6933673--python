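# tfmodminer

Mining transcription-factor (TF) regulatory modules from TF-binding
data, expression compendia and confidence-weighted protein-interaction
networks — and using them to explain the notoriously low overlap between
ChIP binding signals and TF-knockout regulation.

## The science

Most TF→gene binding signals show no expression change when the bound TF
is knocked out.  A major explanation is functional redundancy: TFs that
cooperate in a regulatory module back each other up, so single deletions
are masked.  `tfmodminer` mines such modules in three stages:

1. **Candidate search** — expression rows are reduced by PCA to three
   components; for each gene, k-means (k = 2 … number of binding TFs)
   groups its binding TFs into co-expressed candidate sets.
2. **Module mining** — on the interaction network weighted by
   w(e) = 1 − confidence(e), each candidate set is connected by an
   approximate minimum-cost Steiner tree (Kou–Markowsky–Berman, cost ≤ 2×
   optimum), recruiting non-TF *mediator proteins* where that is cheaper.
3. **Noise reduction** — each module's edge confidences are tested
   against all network edges with a one-sided Mann-Whitney U test;
   per-gene Benjamini–Hochberg keeps modules with q ≤ 0.05.

On top of the confident modules the package computes:

* **Functional redundancy scores** per TF,
  FRS(t) = max_{q≠t} 2|F_t∩F_q| / (|F_t|+|F_q|) over annotation-term
  sets (Dice coefficient), with a Welch t-test comparing module members
  vs non-members, and module expression **coherence** (mean pairwise r²).
* **Functional binding targets**: (t, g) is functional if it has direct
  knockout evidence, or if a confident module containing t provides a
  knockout witness and a second binder for g (the redundancy-masked case).
* **Significance suites**: hypergeometric GO enrichment with log and
  odds-ratio summary scores, core/neighbor protein-complex interaction
  prevalence, and per-condition expression-coherence rank-sum contests.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Generate a synthetic dataset with two planted 3-TF modules (each wired
through a mediator hub, with knockout evidence restricted to one TF per
module — the masking effect), then run the pipeline:

```sh
tfmodminer simulate --out-dir demo --seed 1
tfmodminer run --binding demo/binding.tsv --expression demo/expression.tsv \
    --network demo/network.tsv --knockout demo/knockout.tsv \
    --out-dir demo_out --seed 1
```

which prints the run report

```json
{
  "n_binding_pairs": 212,
  "n_candidate_sets": 104,
  "n_mined_modules": 86,
  "n_confident_modules": 23,
  "n_functional_pairs": 30,
  ...
}
```

212 thresholded binding pairs produced 104 co-expressed candidate sets,
86 distinct mined modules, and 23 that survive the confidence filter.
The top confident module recovers a planted one exactly — terminals
`TF000,TF001,TF002`, mediator `MED00`, cost 0.09 (three edges at
confidence 0.97), q = 0.027.  The functional-target accounting:

```sh
tfmodminer targets --binding demo/binding.tsv --knockout demo/knockout.tsv \
    --modules demo_out/modules_confident.tsv --output demo_out/functional_pairs.tsv
# 212 binding pairs: 10 knockout-inferred (4.7%), 20 pure module-inferred (9.4%),
# union 30 (14.2%); 6 TFs with >= 1 functional target
```

The 10 knockout-inferred pairs are the direct binding ∩ knockout
overlap; the 20 pure module-inferred pairs are exactly the binding pairs
of the planted modules' *other* TFs on the shared targets — the pairs the
knockout screen missed because of redundancy.  The same stages are
available individually (`candidates`, `mine`, `filter`, `frs`,
`evaluate`) and as library functions.

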