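# protsig

Protein-signature discovery for two-class tumor subtyping from RPPA
(reverse-phase protein array) expression profiles.

Distinguishing lung adenocarcinoma (LUAD) from lung squamous cell
carcinoma (LUSC) — or any pair of tumor subtypes — from a panel of a few
hundred protein markers is a small-n, correlated-feature selection
problem. `protsig` implements a three-stage marker-discovery pipeline for
bioinformaticians working with TCPA-level-4-style protein tables plus
TCGA-style clinical annotations:

1. **SNR pre-filter.** Each protein is scored by the two-class
   signal-to-noise ratio
   `SNR = (μ₁ − μ₂) / (σ₁ + σ₂)`
   (class means over the sum of class standard deviations) and kept when
   `|SNR|` exceeds a threshold (default 0.4).
2. **Binary particle swarm optimization (BPSO) wrapper selection.** A
   swarm of bit-vectors searches protein subsets. Velocities follow the
   classical PSO rule
   `v ← w·v + c₁R₁(pbest − x) + c₂R₂(gbest − x)`
   (defaults w = 0.5, c₁ = 1, c₂ = 2, 500 particles × 50 iterations) and
   each bit is resampled to 1 with probability `S(v) = 1/(1+e^(−v))`.
   Fitness is stratified cross-validated accuracy of a simple classifier
   (default 5-NN) on the masked features, minus a small subset-size
   penalty.
3. **PC-stable network learning.** A Bayesian-network structure (CPDAG)
   is learned over the selected proteins plus the class variable by
   order-independent conditional-independence testing (Fisher-z partial
   correlations by default, discretized G² optionally), collider
   orientation from separation sets, and Meek-rule closure. Proteins
   adjacent to the class node are reported as the *direct markers* of the
   subtype.

Downstream validation covers Wilcoxon rank-sum group differences,
Spearman correlation with tumor stage, univariate Cox
proportional-hazards regression, Kaplan-Meier curves with log-rank
tests, and PCA / t-SNE embedding reports. A synthetic-data module
generates expression matrices with planted effect sizes, structural
equation models with known CPDAGs, and Weibull proportional-hazards
survival data, so every stage is testable against ground truth.

## Worked example

Simulate a cohort where the subtype directly drives two proteins (which
in turn drive two more), then run the full discovery pipeline:

```python
import numpy as np, pandas as pd
from protsig import (SyntheticConfig, generate_dag_data, ProteinMatrix,
                     SubtypeSignatureModel, BPSOParams)

edges = [("class", "EGFR_pY1068", 2.0), ("class", "INPP4B", -2.0),
         ("EGFR_pY1068", "STAT3_pY705", 0.9), ("INPP4B", "AKT_pS473", 0.9)]
cfg = SyntheticConfig(n_per_class=200, m_proteins=20, dag_spec=edges, seed=42)
df, _ = generate_dag_data(cfg)
labels = np.where(df["class"] > 0.5, "LUSC", "LUAD")
pm = ProteinMatrix(df.drop(columns=["class"]),
                   pd.Series(labels, index=df.index), classes=("LUAD", "LUSC"))

model = SubtypeSignatureModel(pm, snr_threshold=0.4,
                              bpso_params=BPSOParams(n_particles=40, n_iterations=20),
                              alpha=0.01)
results = model.fit(seed=0)
print(results.summary())
```

```
Protein signature discovery
================================================================
Samples: 400  (LUAD: 198, LUSC: 202)
Proteins: 24
Seed: 0
----------------------------------------------------------------
SNR filter (|SNR| > 0.4): 4 proteins
BPSO wrapper selection: 2 proteins (fitness 0.9050, 20 iterations)
PC-stable (alpha=0.01, fisher_z): 2 edges
----------------------------------------------------------------
Direct markers of the class node:
  EGFR_pY1068      undirected   SNR -1.027
  INPP4B           undirected   SNR +0.841
================================================================
```

The SNR filter keeps the four subtype-dependent proteins (the two direct
targets and their two downstream partners); the wrapper search narrows
to the two proteins that carry all the class information; PC-stable
confirms both as neighbors of the class node. With only two markers and
no collider pattern the class edges stay undirected — adjacency, not
arrow direction, is the marker call. `results.group_tests()` then shows
both markers separating the classes at p < 1e-38 by Wilcoxon rank-sum.

The same object fits real tables:

```python
model = SubtypeSignatureModel.from_dataframe(df, class_col="Cancer_Type",
                                             classes=("LUAD", "LUSC"))
```

which subsets to the two classes, drops proteins missing in more than
half the samples, and mean-imputes the rest before fitting.

A command-line interface mirrors the library
(`protsig preprocess | snr | bpso | bn | simulate | run`); `protsig run
--config run.json` executes all stages and writes per-stage TSV/JSON
artifacts plus a run report.

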