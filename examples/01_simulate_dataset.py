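"""Simulate a two-subline dataset and write every artifact to disk.

Builds a small emulation of the euploid/aneuploid design — two sublines
with subgenome copy numbers S:2/L1:1/L2:1 (DV1_8) and S:2/L1:2/L2:2
(DV1_10), six WGS and three RNA libraries per subline — and writes the
annotation (GFF3), featureCounts-style count tables, library metadata,
the truth table and the configuration.
"""

import tempfile

import karyonorm as kn
from karyonorm import io

config = kn.SimConfig(n_genes={"S": 100, "L1": 100, "L2": 100}, seed=1)
outdir = tempfile.mkdtemp(prefix="karyonorm_example_")
paths = io.write_dataset(outdir, config)

print(f"dataset written to {outdir}:")
for name, path in paths.items():
    print(f"  {name:14s} {path}")

genes, truth, wgs, rna = kn.simulate_dataset(config)
print(f"\n{len(genes)} genes on {truth['scaffold'].nunique()} scaffolds")
print("special genes:", {
    "trans_de": int(truth["is_trans_de"].sum()),
    "compensated": int(truth["is_compensated"].sum()),
    "collapsed": int((truth["collapse_factor"] > 1).sum()),
    "low_coverage": int(truth["is_low_coverage"].sum()),
})
print("\nWGS counts (first 3 genes, first 4 libraries):")
print(wgs.counts.iloc[:3, :4])
# Counts are negative-binomial draws whose means are each gene's share of
# the library's read budget: length x copy number for WGS, rate x copy
# number x regulatory multiplier for RNA.
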