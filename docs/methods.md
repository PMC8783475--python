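# Methods

## Problem and model

A paired-end RNA-Seq fragment is sequenced from both ends: one mate matches
the transcript's sense strand, the other its reverse complement. A
strand-specific protocol (e.g. dUTP-based) fixes which file holds the sense
mate — FR when file 1 does, RF when file 2 does — while an unstranded
protocol assigns it with probability ½ per fragment. The library's
strandedness is therefore estimable from a modest sample of read pairs: each
determinable pair is a Bernoulli draw between FR and RF, and the *stranded
proportion* max(n_FR, n_RF)/(n_FR+n_RF) estimates max(p, 1−p) for the
underlying layout probability p.

## Read assignment: strand-aware k-mer voting

Only the sense k-mers of the transcriptome are indexed (2 bits/base packed
into a uint64, k odd so no k-mer is its own reverse complement). For a read
of length L, m = L−k+1 windows are probed twice: the forward codes give the
sense votes v_s, the codes of the reverse-complemented read the antisense
votes v_a. With v = max(v_s, v_a):

- **UNMAPPED** if v < f·m (too little transcriptome support);
- **AMBIGUOUS_STRAND** if both orientations reach f·m and |v_s − v_a| ≤ 1
  (palindromic or low-complexity sequence should not vote a strand);
- **ASSIGNED** otherwise, to the orientation with strictly more votes; the
  candidate transcripts are the intersection of id-sets over the winning
  orientation's matching k-mers, falling back to their union (flagged
  multi-transcript) when the intersection is empty, as for junction reads
  spanning isoforms. Orientation is trusted either way because it derives
  from vote counts, not id-sets.

Defaults: k = 31, vote threshold f = 0.25 — about one tolerated
substitution error per 100 bases while random 31-mer matches are essentially
impossible (4³¹ ≈ 4.6·10¹⁸ keys). Both are flags. This exact-match voting
deliberately replaces full pseudoalignment: the downstream statistic needs
only (mapped-or-not, orientation), not abundances, so mismatch-tolerant
alignment buys nothing at 200,000-read scale.

Pair classification is a total decision table: opposite mate orientations
give FR/RF by which mate is sense; a single assigned mate still classifies
(mate-1 sense → FR, mate-2 sense → RF, antisense mirrored) to keep usable
pairs from libraries with one weak mate; concordant-orientation mates
(both sense), any ambiguous mate, or mates on disjoint transcript sets are
FAILED; nothing assigned is UNMAPPED. All decisions are made in transcript
space, so a GTF is never required for the verdict — it only enables
RSeQC-notation code strings ("1++,2+-" etc.) in reports.

## Decision thresholds

The verdict uses strict inequalities: stranded above 0.9, unstranded below
0.6, inconclusive at or between the cutoffs. The proportion's denominator is
the determinable pairs (n_FR + n_RF) by default; FAILED pairs are reported
as a separate fraction (warning above 0.2) so that mapping quality cannot
masquerade as unstrandedness. `--denominator total` switches to all sampled
pairs for users who want the conservative reading. Additional warnings:
aligned fraction below 0.1 (wrong or incomplete reference — the verdict is
then meaningless), fewer than 1,000 determinable pairs (estimate noisy; at
p=0.5 the binomial sd at n=1,000 is 1.6 percentage points). A Wilson score
99% interval on the proportion is attached for reporting only; verdicts
never consult it.

By default 200,000 pairs are sampled from the head of the files —
deterministic, and at that size the 3σ sampling half-width of percent
stranded is 100·3·√(0.25/200000) ≈ 0.34 points, comfortably inside the
0.9/0.6 margins. Reservoir sampling (seeded, uniform) is available for
files with positional biases; head mode stops reading once the sample is
full, so record-count mismatches past that point go unnoticed (reservoir
mode scans everything and always detects them).

## Simulator

The simulator is the validation instrument, so its defaults are the study
conditions rather than knobs to tune per run: read length 100, fragment
length Normal(250, 25) rounded and clipped to [read_len, transcript length]
(clipping, not rejection — the difference is negligible for transcripts ≥
500 bp), lognormal(0, 1) transcript abundances to emulate realistic
expression skew (uniform mode retained for analytic checks), substitution
errors only (the voting assigner is insensitive to indel realism), and
fragment starts uniform within the transcript. A pair follows the requested
layout with probability p ∈ [0.5, 1] and the opposite layout otherwise;
p < 0.5 is rejected as the mirrored case of the other layout. Synthetic
transcriptomes are i.i.d. uniform bases (GC 0.5), which makes cross-mapping
between transcripts essentially zero — ideal for isolating the classifier's
own behaviour, and deliberately unrealistic about homology: passing tests
bound sampling error and classifier bias, not robustness to gene families,
pseudogenes or rRNA contamination. Ground truth is carried redundantly in
read names (`sim<i>|<transcript>|<FR|RF>|<start>`) and a sidecar TSV.

The genomic-DNA control cuts a random reference into 1 kb features all
labelled '+', then draws each fragment's strand with a fair coin: the true
stranded proportion is exactly ½ by construction, so the pipeline's output
on it measures pure pipeline bias. All generators run off
`numpy.random.default_rng` with explicit seeds and are byte-reproducible.

## Numerical and engineering choices

K-mer membership is a bucketed directory over the sorted code array (top 21
bits → offsets, then a short in-bucket scan) driven by a numba kernel that
rolls the forward and reverse-complement codes across each read in one
pass; a pure-numpy scalar path (`assign_read`) defines the semantics and
the batch path is tested equal to it read-for-read. Reads shorter than k
are UNMAPPED, not errors; windows containing N are skipped but still count
in the threshold denominator m (an unreadable read should not become easier
to assign). The index stores k in its artifact; a conflicting `--kmer` flag
is ignored with a warning. Ties and near-ties in votes never classify a
strand. k is accepted down to 3 for toy references, with a warning below 11.

## Validation study sizes

The shipped checks run the full pipeline at the tool's operating point:
30 unstranded replicates of 200,000 pairs for the precision bound (3× the
replicate sd of percent stranded ≤ 0.5 points), mixture titrations at
200,000 pairs (mean |estimate − mixing-law truth| < 0.1 points), single
200,000-pair runs for the p=0.5, p=1.0 and gDNA calibrations, all on a
seeded 1,000-transcript (500–3,000 bp) synthetic transcriptome.

## Known limitations

Single-end libraries are out of scope (the layout question is defined on
pairs). The assigner has no splice or indel model, so reads spanning
junctions absent from the transcriptome lose votes; with the default f =
0.25 this only matters for heavily degraded references. Multi-sample
aggregation is left to the caller: check at least a few samples per study,
since one inconclusive sample among stranded ones usually means sample
contamination rather than a protocol change. Contamination *source*
identification (which species, which biotype) is outside the tool's remit.
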