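"""Genomic-DNA contamination control: no strand bias over intergenic features.

Reads derived from genomic DNA come from either strand with equal
probability, so when mapped against features all labelled '+', the stranded
proportion must sit at 50%.  A sample whose mRNA check is inconclusive but
whose intergenic reads behave like this is likely contaminated with gDNA.
"""

import math

from strandcheck import build_index, run_on_pairs, simulate_gdna_pairs

pairs, truth, features = simulate_gdna_pairs(
    n_pairs=50_000, region_len=500_000, seed=21
)
index = build_index(features)
report = run_on_pairs(pairs, index)

n_det = report.counts.n_fr + report.counts.n_rf
sigma_pp = 100 * math.sqrt(0.25 / n_det)
print(f"features: {len(features)} x 1 kb, all '+' strand")
print(f"percent stranded: {report.percent_stranded:.3f}%  (3 sigma = {3 * sigma_pp:.3f} pp)")
print(f"verdict: {report.verdict.value}")
print(
    "\n50% within sampling noise confirms genomic fragments carry no strand\n"
    "information — the expected signature of gDNA carry-over."
)
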