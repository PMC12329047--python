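# ptalign

Reference-based pseudotime alignment and activation-state architecture
analysis for single-cell transcriptomes.

Adult-stem-cell-like lineages progress through quiescence (Q), activation
(A), and differentiation (D). Tumors that hijack such lineages — glioblastoma
organizing along the adult neural-stem-cell (v-SVZ) trajectory being the
motivating case — can be understood by *projecting their cells onto the
healthy lineage's pseudotime* instead of clustering each tumor in isolation.
`ptalign` implements that projection and the downstream analyses it enables:

- **Alignment** — each query cell's expression over a set of trajectory
  genes is correlated with pseudotime-binned reference profiles; a small
  multi-layer perceptron trained on the reference's own (self-masked)
  profiles maps these *similarity profiles* to a pseudotime in [0, 1].
  Cycling cells (G2M score > 0.1) are flagged and excluded; heuristics flag
  out-of-distribution cells. Stages follow the printed cutoffs: Q below
  0.282 (dormant below 0.141), A in [0.282, 0.676], D above.
- **Alignment QC** — dynamic time warping of the pseudotime-binned reference
  against the equally binned query gives a correlation matrix; the monotone
  path of maximal mean correlation is the test statistic, compared against
  full pipeline reruns on expression-matched permuted gene sets to give an
  empirical P-value (add-one rule).
- **Expression dynamics** — per gene and sample, expression over pseudotime
  is summarized by a penalized 5-basis B-spline, clipped at zero and
  area-normalized; dynamics differences are scored by the Wasserstein-1
  (Earth Mover's) distance between the unit-area curves, with unexpressed
  genes assigned distance 1. Recurrently dysregulated genes are the top
  tail of the ranked mean distance, cut at the kneedle inflection.
- **Population model** — a linear ODE over (Q, A, D):
  Q→A activation at rate `r_act`; A divides at rate `r_div = 1` into Q+Q
  (probability `p_self`), A+A (`p_amp`), or D+D (otherwise); D is lost at
  `r_death`. The dominant eigenvalue is the growth rate, its eigenvector
  the equilibrium composition; fitting minimizes the Aitchison distance
  between model equilibrium and an observed composition.
- **Synthetic data** — a generator for non-branching lineages with known
  pseudotime, Gaussian-bump gene programs, negative-binomial counts,
  cycling contamination, composition bias, planted dysregulated genes, and
  out-of-distribution cells, so every claim is testable without external
  data.

## Worked example

```python
import numpy as np
from ptalign.synth import SynthConfig, make_reference, make_query_sample, true_trajectory_genes
from ptalign.reference import bin_reference
from ptalign.align import train_predictor, align_query, stage_composition
from ptalign.dtw import permutation_pvalue

cfg = SynthConfig(seed=11, n_cells=300, n_genes=600, n_traj_genes=60)
ref, truth = make_reference(cfg)
genes = true_trajectory_genes(truth)
binned = bin_reference(ref, genes, n_bins=15)
model = train_predictor(ref, binned, genes, seed=11)

query, qtruth = make_query_sample(cfg, n_cells=150, seed=2011)
result = align_query(query, binned, model, cycling=qtruth.cycling)
ok = result.status == "aligned"
print("pearson r:", np.corrcoef(result.pseudotime[ok], qtruth.pseudotime[ok])[0, 1])
print("composition (Q, A, D):", stage_composition(result))

qc = permutation_pvalue(query, ref, binned, genes, n_perm=100, seed=5, model=model)
print("observed DTW score:", round(qc.observed_score, 3), " p =", round(qc.p_value, 4))
```

prints (exactly, given these seeds):

```
pearson r: 0.9926385448857823
composition (Q, A, D): [0.37777778 0.2962963  0.32592593]
observed DTW score: 0.934  p = 0.0099
```

The query's aligned pseudotimes track the generative truth (r = 0.99); the
sample splits roughly evenly across Q/A/D as generated; and the observed
mean correlation along the DTW traceback (0.93) exceeds all 100
expression-matched permutations, giving the minimum attainable p of
1/101 ≈ 0.0099 — the alignment is trustworthy.

The same pipeline is available from the shell:

```sh
ptalign synth --preset reference --seed 0 --out data/
ptalign reference --counts data/reference --pseudotime data/reference/pseudotime.tsv \
    --out bundle.joblib
ptalign align --query data/tumor --reference-bundle bundle.joblib --out aligned.tsv
ptalign qc --query data/tumor --reference-bundle bundle.joblib --n-perm 100 --out qc.json
```

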