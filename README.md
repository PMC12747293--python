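# selscape

Toolkit for genome-wide selection-landscape analysis in prokaryote-style
comparative genomics, exercisable end-to-end on synthetic data:

- **Codon evolution** (`selscape.codon`): GY94-style codon substitution model
  over the 61 sense codons; alignment simulation by exact event sampling on a
  tree; maximum-likelihood estimation of dN/dS (omega), the
  transition/transversion ratio (kappa) and a global branch-length scale with
  fixed topology; a Nei–Gojobori counting estimator as an independent
  cross-check; mutation-count retention filters (≥ 32 mutations per family,
  ≥ 70% of families per lineage) and representative-paralog selection.
- **Decomposition** (`selscape.decompose`): iterative backfitting of the
  additive model `r[L,G] = F[L] + R[G] + e[G,L]` on lineage × gene log dN/dS
  matrices with missing cells, Bonferroni-based outlier removal and refit,
  and per-functional-class decomposition with a concordance table.
- **Tree operations** (`selscape.trees`): rooted phylogenies with Newick I/O,
  phylogenetic depth, detection of branches splitting a tree into two large
  deep subtrees, subtree extraction, boundary-value reliability flags,
  subtree-constraint heterogeneity measures, and a codon-column bootstrap for
  subtree dN/dS.
- **Gene flux** (`selscape.flux`): Fitch-parsimony ancestral presence/absence
  reconstruction (or ingestion of external state tables), branch-wise
  gain/loss counting, and tree-length-normalized gain, loss and flux rates.
- **Statistics** (`selscape.stats`): Spearman correlations with asymptotic
  p-values, bias-corrected and accelerated (BCa) bootstrap confidence
  intervals, subsampling nulls, and per-node correlations mapped onto a
  phylogeny.
- **Synthetic data** (`selscape.synthetic`): random trees with exact
  total-length control, planted additive matrices, two-state gain/loss
  simulation with true ancestral states, and covariates with tunable rank
  correlation to planted factors.
- **Pipeline** (`selscape.pipeline` / `selscape` CLI): YAML-configured
  end-to-end runs with deterministic per-stage seeding and byte-identical
  reruns.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (omega/kappa
recovery, decomposition oracle equivalence, planted-parameter recovery, flux
and split correctness, bootstrap calibration, pipeline determinism); the rest
of the suite covers each module with unit, oracle and property tests.

## CLI

```sh
selscape simulate --n-lineages 60 --n-genes 120 --seed 1 --out data/
selscape simulate-codon --omega 0.3 --kappa 2 --codons 300 --seed 1 --out aln.fna
selscape dnds --alignment aln.fna --tree tree.nwk
selscape decompose --matrix data/matrix.tsv --out fit/
selscape split --tree tree.nwk --min-tips 20 --min-depth 0.2
selscape flux --tree tree.nwk --pam pam.fasta --family-map fam.tsv
selscape correlate --table table.tsv --bootstrap 1000 --seed 1
selscape pipeline --config config.yaml --out run/
selscape validate-recovery --n-alignments 200 --seed 7
```

A pipeline config looks like:

```yaml
seed: 1
n_bootstrap_bca: 1000
subsample_draws: 10000
subsample_n: 19
synthetic:
  n_lineages: 300
  n_genes: 200
  residual_sd: 0.3
  missing_fraction: 0.2
  covariate_rho: 0.3
  n_classes: 4
  flux_families: 200
```

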