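"""Cohort-level comparison: genotype classes, V-J pair junctions, heatmap order.

Simulates two MHCII alleles crossed with two fixed TCR-beta chains, then
summarises pairwise overlap by comparison class, lists clonotypes public to
all genotypes, runs a per-V-J-pair junction comparison (with the >= 5 distinct
CDR3s admissibility filter), and orders samples by UPGMA on log2
counts-per-10^4 TRAV usage distances.
"""

import pandas as pd

from tcrarep import (
    CohortDesign,
    admissible_vj_pairs,
    hierarchical_order,
    nregion_comparison,
    pairwise_matrix,
    shared_sequence_report,
    summarize_by_class,
    usage_distance_matrix,
    usage_table,
)
from tcrarep.simulate import Genotype, SimulationConfig, simulate_repertoires

config = SimulationConfig(
    seed=19,
    genotypes=(
        Genotype("b", "DObWT"),
        Genotype("f", "DObWT"),
        Genotype("b", "DOb48A"),
    ),
    n_mice_per_genotype=2,
    n_v_segments=6,
    n_j_segments=4,
    acceptance_rate=0.3,
    n_cells=800,
    depth=4000,
)
repertoires, _ = simulate_repertoires(config)
design = CohortDesign(repertoires)

matrix, _results = pairwise_matrix(design, "chao_jaccard")
for s in summarize_by_class(matrix, design, "chao_jaccard"):
    sem = f" +/- {s.sem:.3f}" if s.sem is not None else ""
    print(f"{s.comparison_class}: mean Chao-Jaccard {s.mean:.3f}{sem} "
          f"over {s.n_pairs} pairs")
# Same-genotype pairs share selected clonotypes; changing either the MHCII
# allele or the partner TCR-beta collapses the overlap.

public = shared_sequence_report(design)
print(f"clonotypes present in every genotype: {len(public)}")

pairs = admissible_vj_pairs(design, min_unique=5)
print(f"V-J pairs with >=5 distinct CDR3s in every sample: {len(pairs)}")
if pairs:
    v, j = pairs[0]
    summaries, _m, _log = nregion_comparison(design, v, j, min_unique=5)
    for s in summaries:
        print(f"  {v}/{j} {s.comparison_class}: junction-set Jaccard {s.mean:.3f}")

counts = {
    rep.sample_id: pd.Series(
        usage_table(rep, "TRAV").counts, index=list(usage_table(rep, "TRAV").labels)
    )
    for rep in repertoires
}
distances = usage_distance_matrix(counts, pseudocount=1.0)
order, _linkage, newick = hierarchical_order(distances)
print("UPGMA leaf order for the usage heatmap:", " ".join(order))
print("tree:", newick)
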