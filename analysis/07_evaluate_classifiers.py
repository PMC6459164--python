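#!/usr/bin/env python
"""How well do the called DEGs separate the two conditions?

PCA explained-variance proportions and repeated 10-fold naive-Bayes CV AUC,
computed on the purified cohort with the called DEG set versus an
equally-sized random gene set.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hdcn import io as hio
from hdcn.containers import ExpressionMatrix
from hdcn.evaluation import nb_cv_auc, pca_explained_variance

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA, OUT = ROOT / "data", ROOT / "tables"

purified = hio.read_expression_matrix(OUT / "purified.tsv",
                                      OUT / "purified_groups.tsv")
cohort = hio.read_expression_matrix(DATA / "cohort_matrix.tsv",
                                    DATA / "cohort_groups.tsv")
reference = cohort.subset(purified.gene_ids, cohort.reference_samples)
combined = ExpressionMatrix(
    pd.concat([purified.values, reference.values], axis=1),
    {**purified.groups, **reference.groups},
)

degs = pd.read_csv(OUT / "degs.tsv", sep="\t").set_index("gene_id")
deg_genes = list(degs.index[degs["call"] != "none"])
rng = np.random.default_rng(1)
random_genes = list(rng.choice(
    [g for g in combined.gene_ids if g not in set(deg_genes)],
    size=len(deg_genes), replace=False))

pca = pca_explained_variance(combined, deg_genes, k=3)
print(f"PCA with {len(deg_genes)} called DEGs: "
      f"PC1 {pca[0]:.3f}, PC2 {pca[1]:.3f}, PC3 {pca[2]:.3f}")

rows = []
for name, feats in (("called_degs", deg_genes), ("random_genes", random_genes)):
    auc, sd = nb_cv_auc(combined, feats, n_folds=10, n_repeats=50, seed=1)
    rows.append({"feature_set": name, "n_features": len(feats),
                 "auc_mean": auc, "auc_sd": sd})
    print(f"naive-Bayes 10-fold CV AUC [{name}]: {auc:.3f} +- {sd:.3f}")
pd.DataFrame(rows).to_csv(OUT / "classification_auc.tsv", sep="\t", index=False)
pd.DataFrame([{"pc1": pca[0], "pc2": pca[1], "pc3": pca[2]}]).to_csv(
    OUT / "pca_proportions.tsv", sep="\t", index=False)
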