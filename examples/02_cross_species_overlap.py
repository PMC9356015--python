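"""Test whether the DEG overlap between two species exceeds chance.

DEGs are called in both pseudo-species (adjusted p in the primary cohort,
uncorrected p in the secondary one), mapped through the 1:1 orthology, and
the intersection is compared with 100,000 random same-size draws from a
fixed gene universe.
"""

from degnet.deg import differential_expression, filter_low_counts, select_degs
from degnet.overlap import (
    exclude_region_genes, hypergeometric_overlap_p, map_orthologs,
    overlap_sets, permutation_overlap_p,
)
from degnet.synthetic import SimConfig, simulate_all

config = SimConfig(n_genes=2000, ppi_n_edges=4000, module_sizes=(15, 15, 15, 15),
                   n_prenatal_max=20, seed=1)
bundle = simulate_all(config)

human = select_degs(differential_expression(
    filter_low_counts(bundle.counts["human"])), "adjusted")
mouse = select_degs(differential_expression(
    filter_low_counts(bundle.counts["mouse"])), "raw")
mouse_mapped = map_orthologs(mouse, bundle.orthology)

observed = overlap_sets([human, mouse_mapped]).kway
result = permutation_overlap_p([len(human), len(mouse_mapped)], observed,
                               universe_size=config.n_genes,
                               n_samplings=100_000, seed=1)
analytic = hypergeometric_overlap_p(len(human), len(mouse_mapped), observed,
                                    config.n_genes)
outside = exclude_region_genes(human & mouse_mapped, set(config.region_genes()))

print(f"human DEGs (adjusted): {len(human)}; mouse DEGs (raw): {len(mouse_mapped)}")
print(f"shared genes: {observed} ({len(outside)} outside the deletion region)")
print(f"permutation p (B={result.n_samplings:,}): {result.p_empirical:.2e}")
print(f"exact hypergeometric tail (2-set check): {analytic:.2e}")
print("-> the shared set is far larger than random same-size draws produce;")
print("   the empirical p floors at 1/(B+1) while the analytic tail shows how")
print("   extreme the observed overlap really is.")
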