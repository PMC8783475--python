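"""Strand-configurable paired-end read simulator with ground truth.

Generates synthetic transcriptomes and read pairs whose layout (FR or RF) is
drawn per pair with a controlled probability ``strandedness_p``: 1.0 gives a
pure strand-specific library, 0.5 an unstranded one, and intermediate values
emulate partially stranded mixtures.  Ground truth travels both in the read
names (``sim<i>|<transcript>|<FR|RF>|<start>``) and as TruthRecord objects /
a sidecar TSV, so any downstream stage can be checked against it.

Every operation is driven by ``numpy.random.default_rng`` on an explicit
seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .index import revcomp
from .io import ReadPair, Transcript, write_fastq_pair

log = logging.getLogger("strandcheck")

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated paired-end sample.

    ``strandedness_p`` is the probability that a pair follows ``layout``
    (the stranded direction); the remainder follow the opposite layout, so
    p=1.0 is a pure stranded library and p=0.5 an unstranded one.  Fragment
    lengths are Normal(mean, sd), rounded and clipped into
    [read_len, transcript length].
    """

    n_pairs: int
    read_len: int = 100
    frag_len_mean: float = 250.0
    frag_len_sd: float = 25.0
    strandedness_p: float = 1.0
    layout: str = "FR"
    error_rate: float = 0.0
    abundance_model: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.strandedness_p <= 1.0:
            raise ValueError(
                "strandedness_p must be in [0.5, 1]; below 0.5 is the "
                "mirrored case — use the opposite layout instead"
            )
        if self.layout not in ("FR", "RF"):
            raise ValueError(f"layout must be FR or RF, got {self.layout!r}")
        if self.frag_len_mean < self.read_len:
            raise ValueError("frag_len_mean must be >= read_len")
        if self.abundance_model not in ("uniform", "lognormal"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted pair."""

    name: str
    transcript_id: str
    orientation: str  # "FR" or "RF"
    start: int
    frag_len: int


def make_transcriptome(
    n: int, len_range: tuple[int, int], seed: int, prefix: str = "tx"
) -> list[Transcript]:
    """n i.i.d. uniform-base random transcripts with lengths in ``len_range``.

    Uniform bases give GC ~ 0.5 and essentially no repeated k-mers between
    transcripts, so reads map back to their source unambiguously — the ideal
    regime for checking the classifier itself.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = len_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad length range {len_range}")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n)
    width = max(4, len(str(n)))
    out = []
    for i, L in enumerate(lengths, start=1):
        codes = rng.integers(0, 4, size=int(L), dtype=np.uint8)
        seq = _DECODE[codes].tobytes().decode("ascii")
        out.append(Transcript(id=f"{prefix}{i:0{width}d}", sequence=seq))
    return out


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(codes)) < rate)[0]
    if len(hits) == 0:
        return seq
    base_idx = {65: 0, 67: 1, 71: 2, 84: 3}
    for i in hits:
        cur = base_idx.get(int(codes[i]), 0)
        codes[i] = _DECODE[(cur + int(rng.integers(1, 4))) % 4]
    return codes.tobytes().decode("ascii")


def simulate_pairs(
    transcriptome: Sequence[Transcript], spec: SimSpec
) -> tuple[list[ReadPair], list[TruthRecord]]:
    """Draw ``spec.n_pairs`` read pairs from a transcriptome.

    Per pair: a transcript is chosen by the abundance model (lognormal
    weights by default, emulating realistic expression skew), a fragment
    placed uniformly, and the layout coin flipped with ``strandedness_p``.
    Mate 1 and mate 2 are the two fragment ends; the antisense mate is
    reverse-complemented.  Substitution errors (if any) are applied i.i.d.
    """
    if not transcriptome:
        raise ValueError("transcriptome is empty")
    tx_lens = np.array([len(t.sequence) for t in transcriptome])
    if (tx_lens < spec.read_len).all():
        raise ValueError(
            f"every transcript is shorter than read_len={spec.read_len}"
        )
    usable = np.nonzero(tx_lens >= spec.read_len)[0]
    rng = np.random.default_rng(spec.seed)

    if spec.abundance_model == "uniform":
        weights = np.ones(len(usable))
    else:
        weights = rng.lognormal(mean=0.0, sigma=1.0, size=len(usable))
    weights /= weights.sum()

    n = spec.n_pairs
    tx_choice = usable[rng.choice(len(usable), size=n, p=weights)]
    frag = np.rint(
        rng.normal(spec.frag_len_mean, spec.frag_len_sd, size=n)
    ).astype(np.int64)
    frag = np.clip(frag, spec.read_len, tx_lens[tx_choice])
    start = np.floor(
        rng.random(n) * (tx_lens[tx_choice] - frag + 1)
    ).astype(np.int64)
    follows_layout = rng.random(n) < spec.strandedness_p
    other = "RF" if spec.layout == "FR" else "FR"

    pairs: list[ReadPair] = []
    truth: list[TruthRecord] = []
    R = spec.read_len
    for i in range(n):
        tx = transcriptome[int(tx_choice[i])]
        s, f = int(start[i]), int(frag[i])
        fragment = tx.sequence[s : s + f]
        sense_mate = fragment[:R]
        anti_mate = revcomp(fragment[-R:])
        orient = spec.layout if follows_layout[i] else other
        if orient == "FR":
            seq1, seq2 = sense_mate, anti_mate
        else:
            seq1, seq2 = anti_mate, sense_mate
        if spec.error_rate > 0:
            seq1 = _apply_errors(seq1, rng, spec.error_rate)
            seq2 = _apply_errors(seq2, rng, spec.error_rate)
        name = f"sim{i:06d}|{tx.id}|{orient}|{s}"
        pairs.append(ReadPair(name=name, seq1=seq1, seq2=seq2))
        truth.append(
            TruthRecord(
                name=name,
                transcript_id=tx.id,
                orientation=orient,
                start=s,
                frag_len=f,
            )
        )
    return pairs, truth


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("name\ttranscript_id\torientation\tstart\tfrag_len\n")
        for t in truth:
            out.write(
                f"{t.name}\t{t.transcript_id}\t{t.orientation}\t{t.start}\t{t.frag_len}\n"
            )


def simulate_to_files(
    transcriptome: Sequence[Transcript],
    spec: SimSpec,
    fastq1: str | Path,
    fastq2: str | Path,
    truth_tsv: str | Path | None = None,
) -> list[TruthRecord]:
    """File-emitting wrapper over :func:`simulate_pairs`."""
    pairs, truth = simulate_pairs(transcriptome, spec)
    write_fastq_pair(pairs, fastq1, fastq2)
    if truth_tsv is not None:
        write_truth(truth, truth_tsv)
    return truth


def mix_samples(
    pairs_a: Sequence[ReadPair],
    pairs_b: Sequence[ReadPair],
    ratio: float,
    total_pairs: int,
    seed: int,
) -> list[ReadPair]:
    """Sample ``ratio`` of ``total_pairs`` from A and the rest from B.

    Without replacement from each pool, interleaved in random order;
    reproducible per seed.  Mixing a pure stranded pool with an unstranded
    one at ratio r yields an expected percent stranded of 100·(r + (1−r)/2).
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0, 1]")
    n_a = int(np.floor(ratio * total_pairs))
    n_b = total_pairs - n_a
    if n_a > len(pairs_a):
        raise ValueError(
            f"pool A has {len(pairs_a)} pairs, {n_a} requested ({n_a - len(pairs_a)} short)"
        )
    if n_b > len(pairs_b):
        raise ValueError(
            f"pool B has {len(pairs_b)} pairs, {n_b} requested ({n_b - len(pairs_b)} short)"
        )
    rng = np.random.default_rng(seed)
    take_a = rng.choice(len(pairs_a), size=n_a, replace=False)
    take_b = rng.choice(len(pairs_b), size=n_b, replace=False)
    mixed = [pairs_a[int(i)] for i in take_a] + [pairs_b[int(i)] for i in take_b]
    order = rng.permutation(len(mixed))
    return [mixed[int(i)] for i in order]


def simulate_gdna_pairs(
    n_pairs: int,
    region_len: int = 1_000_000,
    read_len: int = 100,
    frag_len_mean: float = 250.0,
    frag_len_sd: float = 25.0,
    feature_len: int = 1000,
    seed: int = 0,
) -> tuple[list[ReadPair], list[TruthRecord], list[Transcript]]:
    """Genomic-DNA control: fair-coin strand fragments vs a '+'-only reference.

    Emulates profiling intergenic regions: a random reference sequence is cut
    into fixed-length features all labelled '+', and each fragment's source
    strand is a fair coin — so the true stranded proportion is exactly 0.5
    and any deviation downstream is the pipeline's own bias.
    """
    if region_len < max(feature_len, int(frag_len_mean)):
        raise ValueError("region_len too short for the fragment model")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=region_len, dtype=np.uint8)
    region = _DECODE[codes].tobytes().decode("ascii")
    n_feat = region_len // feature_len
    width = max(4, len(str(n_feat)))
    features = [
        Transcript(
            id=f"intergenic{i + 1:0{width}d}",
            sequence=region[i * feature_len : (i + 1) * feature_len],
            genome_strand="+",
        )
        for i in range(n_feat)
    ]
    # fair strand coin == unstranded library over the '+'-labelled features
    spec = SimSpec(
        n_pairs=n_pairs,
        read_len=read_len,
        frag_len_mean=frag_len_mean,
        frag_len_sd=frag_len_sd,
        strandedness_p=0.5,
        layout="FR",
        error_rate=0.0,
        abundance_model="uniform",
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    pairs, truth = simulate_pairs(features, spec)
    return pairs, truth, features


def parse_truth_name(name: str) -> tuple[str, str, int]:
    """(transcript_id, orientation, start) from a simulated read name."""
    _, tx, orient, start = name.split("|")
    return tx, orient, int(start)
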