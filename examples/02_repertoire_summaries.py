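"""Build a clonotype repertoire and print its descriptive summaries.

Shows segment-usage percentages (abundance-weighted: percent of reads, i.e.
of cells), the CDR3 length distribution, mean N-region bases,
and the positional amino-acid profile for one CDR3 length.
"""

from tcrarep import (
    cdr3_length_distribution,
    mean_cdr3_length,
    mean_n_bases,
    positional_aa_frequency,
    usage_table,
)
from tcrarep.simulate import Genotype, SimulationConfig, simulate_repertoires

config = SimulationConfig(
    seed=11,
    genotypes=(Genotype("b", "DObWT"),),
    n_mice_per_genotype=1,
    n_cells=1500,
    depth=8000,
)
repertoires, _mice = simulate_repertoires(config)
rep = repertoires[0]
print(f"{rep.sample_id}: {rep.n_clonotypes} clonotypes from {rep.total_reads} reads")

usage = usage_table(rep, "TRAV", weighting="reads")
top = sorted(zip(usage.labels, usage.percents), key=lambda t: -t[1])[:3]
print("top TRAV usage (% of reads):",
      ", ".join(f"{label} {pct:.1f}%" for label, pct in top))

hist = cdr3_length_distribution(rep)  # unique-clonotype weighting
print(f"CDR3 lengths span {hist.index.min()}-{hist.index.max()} aa, "
      f"mean {mean_cdr3_length(rep):.2f} aa over unique clonotypes")
print(f"mean untemplated N bases per clonotype: {mean_n_bases(rep):.2f}")

length = int(hist.idxmax())
mat = positional_aa_frequency(rep, length)
pos4 = mat.loc[4].sort_values(ascending=False)
print(f"most common residue at position 4 of {length}-mer CDR3s: "
      f"{pos4.index[0]} ({100 * pos4.iloc[0]:.1f}%)")
# Positions are 1-based from the invariant cysteine; each row of the matrix
# is a probability vector over the 20 amino acids.
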