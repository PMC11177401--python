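"""mtDNA copy number from read fractions and repeat copies from depth.

The copy ratio R = f_mt * G_nuc / L_mt converts the fraction of sequencing
reads that are mitochondrial into mtDNA copies per nuclear genome. A tandem
repeat assembled at single copy shows up as a depth plateau; its height over
the flanking depth estimates the per-genome repeat copy number.
"""

import numpy as np

from mitohet import copynum

# the printed extremes of the matriline read fractions
for f_mt in (2e-5, 3e-4):
    r = copynum.copy_ratio(f_mt, g_nuc=3.5e9, l_mt=14202)
    print(f"mt read fraction {f_mt:.4%} -> {r:.1f} mtDNA copies per nuclear genome")

# a depth plateau: 3 repeat copies at 100x flanking coverage
rng = np.random.default_rng(1)
depth = rng.poisson(100, 14202).astype(float)
depth[1532:1666] = rng.poisson(300, 134)
est = copynum.repeat_copy_number(depth, (1533, 1666), flank=1000, circular=True)
print(f"repeat depth ratio: {est:.2f} copies per genome (simulated truth 3)")

profile = copynum.windowed_depth(depth, 25)
print(
    f"windowed depth: {len(profile.window_means)} windows of 25 bp, "
    f"median {np.median(profile.window_means):.0f} reads"
)
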