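"""Call parent-of-origin methylation regions (poeMRs) from per-CpG tests.

Builds a toy table of tested CpGs in which one block carries a strong
maternal-specific methylation signal, runs the per-CpG binomial model,
and calls methylation regions from the adjusted p-values.
"""

import numpy as np
import pandas as pd

from allelescope import asetest, regions

rng = np.random.default_rng(1)

samples = pd.DataFrame([
    {"sample_id": f"{d}_{sex}{i}", "individual": f"{d}_{sex}{i}",
     "tissue": "brain", "stage": "F70", "sex": sex, "cross_direction": d}
    for d in ("DxL", "LxD") for sex in ("F", "M") for i in (1, 2, 3)])
design = asetest.build_design(samples)

positions = np.sort(rng.choice(20_000, size=60, replace=False))
in_region = (positions >= 5_000) & (positions <= 6_200)
print(f"{in_region.sum()} of 60 CpGs lie in the differentially "
      "methylated block [5000, 6200]")

cov = 25
m_rows, u_rows = [], []
for pos, diff in zip(positions, in_region):
    m, u = [], []
    for _, r in design.iterrows():
        if diff:   # maternal allele methylated, paternal unmethylated
            p = 0.9 if r["origin"] == "maternal" else 0.1
        else:
            p = 0.75
        mm = rng.binomial(cov, p)
        m.append(mm)
        u.append(cov - mm)
    m_rows.append(m)
    u_rows.append(u)
obs = [f"{r['sample_id']}.{r['origin']}" for _, r in design.iterrows()]
m_df = pd.DataFrame(m_rows, columns=obs)
u_df = pd.DataFrame(u_rows, columns=obs)

res = asetest.fit_binomial_glm(m_df, u_df, design)
poe = res[res["effect"] == "POE"].copy()
poe["chrom"] = "chr1"
poe["pos"] = positions
mrs = regions.call_methylation_regions(poe.sort_values("pos"), "poeMR")
for r in mrs:
    print(f"poeMR {r.chrom}:{r.start}-{r.end}  n_cpgs={r.n_cpgs}")
# The planted block is recovered as one poeMR spanning its significant
# CpGs; isolated background CpGs never form a region (>=3 consecutive
# significant CpGs within 1.5 kb are required).
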