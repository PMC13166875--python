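# orsel

Tools for asking whether the **adaptive evolution of a multigene family is
associated with trait evolution on a species phylogeny** — the motivating
case being the ant odorant-receptor (OR) repertoire, whose hundreds of
paralogs per genome evolve by rapid duplication, loss, and episodic positive
selection, and whose expansion has been linked to the elaboration of social
organization.

The analytical obstacle is that selection is tested on *gene-tree* branches
(a branch-site dN/dS likelihood-ratio test run by an external tool), while
the hypotheses live on *species-tree* branches ("did positive selection
concentrate on the branch where colony size increased?"). `orsel` bridges
the two:

1. **Reconciliation** — each gene tree is embedded in the species tree by
   duplication–loss (LCA) parsimony, attributing every tested gene branch to
   one species branch. Precomputed reconciliations can be imported from
   NHX-annotated trees.
2. **Transition branches** — ancestral reconstruction of traits (Mk models
   with ER/ARD compared by AIC for discrete traits; Brownian motion for
   continuous ones) identifies species branches with inferred trait changes;
   a curated transitions file can be supplied instead.
3. **Enrichment statistic** — the core test. Gene branches are weighted by
   length relative to their dataset mean (long branches accumulate more
   detectable selection), and a hypergeometric test compares the number of
   significant branches (p < α, default 0.05) landing on transition branches
   against the length-normalized expectation:

   N_w = round(Σ w_b), n_w = round(Σ_{b∈transition} w_b), K = #{p_b < α},
   k = #{p_b < α, b ∈ transition}, X ~ Hypergeom(N_w, K, n_w),
   fold = k / (n_w·K/N_w), p_enrich = P(X ≥ k), p_deplete = P(X ≤ k).

   Convergent transitions are pooled by summing tallies before testing, and
   Benjamini–Hochberg q-values are reported across tests.
4. **Gene-family dynamics** — ancestral copy numbers by Sankoff parsimony
   (linear gain/loss cost; equals Wagner interval parsimony), per-branch
   expansions/contractions, and PGLS regression of per-family counts on
   traits under a Brownian/Pagel-λ covariance, with mostly-single-copy
   families filtered out.
5. **Alignment masking** — adaptive confidence-threshold masking of codon
   alignments (start 0.8, lower by 0.1 until ≤ 20% of codons are masked)
   for use upstream of the selection tests.
6. **Synthetic data** — a seeded generator that evolves gene families down a
   Yule species tree and plants a known fold enrichment of selection on
   designated branches, so calibration and power of the whole pipeline can
   be measured against ground truth.

See `docs/methods.md` for models, defaults, numerical choices, and
limitations.

## Worked example

Simulate a dataset at the default study conditions (8 species, 200 gene
families, baseline 5% significant branches) with a 2-fold enrichment
planted on one internal species branch, then run the pipeline:

```sh
orsel simulate --seed 1 --n-gene-trees 200 --fold 2.0 --out demo/data
cat > demo/cfg.yaml <<EOF
species_tree: demo/data/species.nwk
gene_trees: demo/data/gene_trees.tsv
tests: demo/data/tests.tsv
transitions: demo/data/transitions.tsv
out_dir: demo/run
EOF
orsel run --config demo/cfg.yaml
cat demo/run/enrichment.tsv
```

```
label    N_w   K    n_w  k   expected           fold                p_enrich              p_deplete           p_reported            direction   q
planted  2936  146  197  18  9.796321525885558  1.8374243793894722  0.007682723200513948  0.9966085799952322  0.007682723200513948  enrichment  0.007682723200513948
```

Reading the row: the 200 reconciled gene trees contribute a
length-normalized population of N_w = 2936 branches, 146 of them called
significant at α = 0.05. The planted transition branch received a
normalized draw of n_w = 197 branches; 9.8 significant ones were expected
by chance, 18 were observed — an estimated 1.84-fold enrichment (the
planted 2-fold, shrunk slightly because the transition branches are part of
the population), with one-sided enrichment p = 0.0077 (= q, as there is a
single test to correct).

Each stage is also available separately (`orsel reconcile`, `orsel traits`,
`orsel enrich`, `orsel counts`, `orsel pgls`, `orsel mask`) and as library
functions under `orsel.*`, reading and writing the same TSV/Newick formats
that `orsel run` uses, so any stage can be re-run from the on-disk outputs
of the previous one.

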