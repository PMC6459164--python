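#!/usr/bin/env python
"""Generate the synthetic study cohorts used by the downstream analyses.

Writes, under results/data/: a contaminated two-group expression cohort
with planted DEGs, a two-condition co-expression cohort with planted
dependent pairs, a compartment-structured interaction network with planted
relocalization events, and a Dirichlet-multinomial V-J clonotype table with
a group diversity contrast — each next to its ground-truth table.
"""

from pathlib import Path

import pandas as pd

from hdcn import io as hio
from hdcn.simulate import (
    simulate_coexpression_cohort,
    simulate_expression_cohort,
    simulate_network_with_localization,
    simulate_repertoire,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

matrix, truth = simulate_expression_cohort(
    n_genes=500, n_mixed=40, n_reference=40, n_deg=100, seed=SEED
)
hio.write_expression_matrix(matrix, OUT / "cohort_matrix.tsv", OUT / "cohort_groups.tsv")
truth.pi_true.rename_axis("sample_id").reset_index().to_csv(
    OUT / "cohort_truth_pi.tsv", sep="\t", index=False)
pd.DataFrame(sorted(truth.deg_genes.items()),
             columns=["gene_id", "effect_log2"]).to_csv(
    OUT / "cohort_truth_degs.tsv", sep="\t", index=False)
print(f"expression cohort: {len(matrix.gene_ids)} genes, "
      f"{len(matrix.mixed_samples)}+{len(matrix.reference_samples)} samples, "
      f"{len(truth.deg_genes)} planted DEGs, "
      f"pi in [{truth.pi_true.min():.2f}, {truth.pi_true.max():.2f}]")

mm, mr, pair_truth = simulate_coexpression_cohort(
    n_pairs_dependent=20, n_pairs_null=80, n_samples_per_condition=100,
    dependence_form="linear", noise_sd=0.1, seed=SEED)
coex = pd.concat([mm.values, mr.values], axis=1)
from hdcn.containers import ExpressionMatrix

hio.write_expression_matrix(
    ExpressionMatrix(coex, {**mm.groups, **mr.groups}),
    OUT / "coexpr_matrix.tsv", OUT / "coexpr_groups.tsv")
pd.DataFrame(pair_truth.planted_pairs,
             columns=["gene_a", "gene_b", "dependent_condition"]).to_csv(
    OUT / "coexpr_truth_pairs.tsv", sep="\t", index=False)
print(f"co-expression cohort: {len(pair_truth.planted_pairs)} planted pairs "
      f"of {coex.shape[0] // 2}")

graph, ann, lm, lr, reloc_truth = simulate_network_with_localization(
    n_proteins=100, n_relocated=5, n_samples=60, seed=SEED)
hio.write_network(graph, OUT / "network.tsv")
hio.write_annotations(ann, OUT / "annotations.tsv")
hio.write_expression_matrix(lm, OUT / "loc_matrix_mixed.tsv", OUT / "loc_groups_mixed.tsv")
hio.write_expression_matrix(lr, OUT / "loc_matrix_reference.tsv",
                            OUT / "loc_groups_reference.tsv")
pd.DataFrame([(p, s, d) for p, (s, d) in sorted(reloc_truth.relocated.items())],
             columns=["protein", "source", "destination"]).to_csv(
    OUT / "loc_truth_relocations.tsv", sep="\t", index=False)
print(f"localization network: {graph.number_of_edges()} edges, "
      f"{len(reloc_truth.relocated)} planted relocations")

table, groups, high = simulate_repertoire(
    n_samples_per_group=20, concentration_low=5.0, concentration_high=50.0,
    seed=SEED)
hio.write_clonotype_table(table, OUT / "clonotypes.tsv")
groups.rename_axis("sample_id").reset_index().to_csv(
    OUT / "clonotype_groups.tsv", sep="\t", index=False)
print(f"repertoire: {len(table)} clonotype records; "
      f"higher-diversity group = {high}")
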