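"""The length-normalized relative-abundance statistic on a worked table.

abundance(g, s) = (reads/bp of g / sum of reads/bp over genomes)
                x (reads recruited to genomes / reads recruited to all
                   data-rich contigs >= 2 kb) x 100

Two genomes with identical reads/bp that jointly recruit half of the
data-rich reads therefore score 25% each.
"""

import pandas as pd

import magbin as mb

counts = pd.DataFrame(
    {
        "length": [10_000, 10_000, 20_000, 1_500],
        "S1": [100, 100, 200, 999],  # the 1.5 kb contig is below the
        "S2": [50, 200, 250, 999],   # data-rich cutoff and never counts
    },
    index=pd.Index(["gA_c1", "gB_c1", "other", "short"], name="contig_id"),
)
print("counts table:")
print(counts)

table = mb.genome_relative_abundance(
    {"GA": ["gA_c1"], "GB": ["gB_c1"]}, counts)
print("\nper-genome relative abundance (%):")
print(table.frame.round(4))

summary = mb.summarize_abundance(table, n=10)
print("\nper-sample totals:")
print(summary.round(4))
print("\nIn S1 both genomes have 0.01 reads/bp and together recruit half of "
      "the 400 data-rich reads: 25% each.  In S2 the split follows the "
      "genomes' reads/bp ratio (1:4) within the recruited half.")
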