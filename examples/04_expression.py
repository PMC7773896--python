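"""Compare candidate-gene brain expression between strains.

Builds a small FPKM table (three replicates per strain), z-scores rows
for heatmap display, and runs the depth-normalized equal-variance
Student's t-test per gene.
"""
import pandas as pd

from bsasweep import depth_normalize_and_test, zscore_rows

samples = ["wild_1", "wild_2", "wild_3", "dome_1", "dome_2", "dome_3"]
fpkm = pd.DataFrame(
    {
        "wild_1": [42.0, 8.1, 5.0],
        "wild_2": [39.5, 7.6, 5.2],
        "wild_3": [44.2, 8.9, 4.9],
        "dome_1": [12.1, 7.9, 5.1],
        "dome_2": [10.8, 8.3, 5.0],
        "dome_3": [13.0, 7.7, 5.1],
    },
    index=["FAN1", "Pigo", "ASNA1"],
)
depths = pd.Series(  # total mapped reads per library (millions)
    [21.0, 19.5, 20.2, 20.8, 21.5, 19.9], index=samples
)

z, constant = zscore_rows(fpkm)
print("z-scores (per-gene, for heatmap display):")
print(z.round(2))

res = depth_normalize_and_test(
    fpkm, depths, group_a=samples[:3], group_b=samples[3:]
)
print("\ndepth-normalized Student's t-test (wild vs domestic):")
print(res[["mean_a", "mean_b", "t", "pvalue"]].round(4))
# FAN1 drops sharply in the domestic strain (small p); ASNA1 shows no
# expression difference — its candidacy rests on the coding change.
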