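"""Simulate a small two-species study and call differentially expressed genes.

Builds a 2,000-gene synthetic universe with 5% planted fold changes and
eight halved-dosage deletion-region genes, then runs the stand-in
differential test (Welch t on log2 CPM) with Benjamini-Hochberg selection.
"""

from degnet.deg import differential_expression, filter_low_counts, select_degs
from degnet.synthetic import SimConfig, generate_counts, plan_truth

config = SimConfig(n_genes=2000, ppi_n_edges=4000, module_sizes=(15, 15, 15, 15),
                   n_prenatal_max=20, seed=1)
truth = plan_truth(config)

matrix, planted = generate_counts(config, "human", truth)
matrix = filter_low_counts(matrix, min_total=10)          # "< 10 reads" rule
table = differential_expression(matrix)                   # lfc, p_raw, p_adj
degs = select_degs(table, regime="adjusted", alpha=0.05)  # BH-adjusted p < 0.05

region = config.region_genes()
print(f"genes tested after low-count filter: {len(table)}")
print(f"DEGs at adjusted p < 0.05: {len(degs)} "
      f"({len(degs & planted)} of {len(planted)} planted genes recovered)")
print(f"mean log2 fold change of the {len(region)} deletion-region genes: "
      f"{table.loc[list(region), 'log2_fold_change'].mean():+.2f}")
print("-> the deletion genes sit near -1 (halved dosage, not transcriptionally")
print("   compensated); with 3 cases vs 4 controls only the strongest planted")
print("   effects survive multiple-testing correction.")
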