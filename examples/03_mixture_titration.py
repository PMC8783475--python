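"""Titrate stranded/unstranded mixtures and recover the mixing law.

Mixes a pure FR-stranded pool with an unstranded pool at ratios r and runs
the checker on each mix.  The estimated percent stranded should follow
100*(r + (1-r)/2): 50% at r=0 up to 100% at r=1.
"""

from strandcheck import (
    SimSpec,
    build_index,
    make_transcriptome,
    mix_samples,
    run_on_pairs,
    simulate_pairs,
)

N = 20_000
transcriptome = make_transcriptome(300, (500, 3000), seed=11)
index = build_index(transcriptome)

stranded, _ = simulate_pairs(
    transcriptome, SimSpec(n_pairs=N, strandedness_p=1.0, seed=12)
)
unstranded, _ = simulate_pairs(
    transcriptome, SimSpec(n_pairs=N, strandedness_p=0.5, seed=13)
)

print("ratio  expected%  estimated%")
for i in range(6):
    r = i / 5
    mixed = mix_samples(stranded, unstranded, r, N, seed=14 + i)
    report = run_on_pairs(mixed, index)
    expected = 100 * (r + (1 - r) / 2)
    print(f"{r:5.1f}  {expected:9.2f}  {report.percent_stranded:10.2f}")
print(
    "\nThe estimate tracks the law of total probability across the whole\n"
    "titration; deviations shrink as 1/sqrt(n) with the sample size."
)
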