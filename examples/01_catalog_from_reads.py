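"""Build a conserved-miRNA count matrix from simulated small-RNA libraries.

Generates the 12-library drought/rehydration design, collapses reads into
distinct sequences, applies the >=10-counts-in-one-library filter, assigns
miRNA identities by exact containment against the mature reference, and
collapses isomiRs to one canonical sequence per miRNA.
"""

from mirstress import (
    SimulationConfig,
    assign_reads,
    collapse_isomirs,
    collapse_reads,
    filter_min_count,
    mean_expression,
    mirna_counts,
    simulate_srna_libraries,
)

config = SimulationConfig(seed=1, n_mirnas=30, n_background_seqs=60, n_transcripts=10)
sim = simulate_srna_libraries(config)

matrix = collapse_reads(sim.reads)
print(f"distinct sequences across 12 libraries: {len(matrix)}")

matrix = filter_min_count(matrix, threshold=10)
print(f"after the >=10-counts filter:           {len(matrix)}")

assignments = collapse_isomirs(assign_reads(matrix, sim.ground_truth.mature_set), matrix)
counts = mirna_counts(assignments, matrix)
n_isomirs = sum(1 for a in assignments if not a.is_canonical)
print(f"conserved miRNAs identified:            {len(counts)} "
      f"(+{n_isomirs} isomiR variants collapsed away)")

# mean expression over one contrast's six libraries (3 control_1 + 3 drought)
libs = sim.sample_sheet.query("condition in ['control_1', 'drought']")["library_id"]
mir = counts.index[0]
print(f"mean expression of {mir} over C1+D: {mean_expression(counts.loc[mir], list(libs)):.2f} reads")
# Each count is the library tally of the canonical mature sequence; the mean
# over the six contrast libraries is the study's per-miRNA expression level.
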