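"""Sensitivity of subgenome assignment to the coverage-ratio thresholds.

Re-assigns genes over a grid of (s_min, l_max) threshold pairs, from
permissive (cr >= 1.30 for S) to stringent (cr >= 1.50), and tabulates how
the S/L/NA split of all genes — and of the DEG set — responds.  On the
L-anchored coverage-ratio scale the S and L clusters sit near 2.0 and 1.0,
well clear of the scanned range, so the classification barely moves.
"""

import karyonorm as kn

config = kn.SimConfig(seed=11)
genes, truth, wgs, rna = kn.simulate_dataset(config)
res = kn.run_pipeline(genes, wgs, rna, contrast=("DV1_8", "DV1_10"))

print(res.scan.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
prop = res.scan["deg_prop_s"]
spread = (prop.max() - prop.min()) / prop.mean()
print(
    f"\nS share among assigned DEGs varies by {spread:.1%} "
    "across the threshold grid — the classification is threshold-robust."
)
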