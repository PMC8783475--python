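"""Readers and writers for transcriptome FASTA, paired FASTQ and GTF strand annotation.

Transcriptome FASTA records are assumed to carry the *sense* (mRNA-orientation)
strand, the universal convention of cDNA FASTA releases.  FASTQ mates are read
in lock-step from the two files of a paired-end run; gzip is detected from the
file's magic bytes, never its extension.
"""

from __future__ import annotations

import gzip
import logging
import random
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

import gffutils
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger("strandcheck")

_NON_ACGTN = re.compile(r"[^ACGTN]")
_VERSION_SUFFIX = re.compile(r"\.\d+$")

DEFAULT_SAMPLE_SIZE = 200_000


class DuplicateTranscriptError(ValueError):
    """Two FASTA records share one transcript id."""


class FastqFormatError(ValueError):
    """Truncated or malformed FASTQ record."""


class PairSyncError(ValueError):
    """Mate files disagree (record counts or read names)."""


class GtfParseError(ValueError):
    """A GTF line could not be parsed."""


@dataclass(frozen=True)
class Transcript:
    """One sense-strand transcript sequence.

    ``genome_strand`` is the strand of the transcript's locus on the genome
    ('+' or '-'), known only when a GTF was supplied; it never affects
    orientation calls, only the optional RSeQC-style code strings.
    """

    id: str
    sequence: str
    gene_id: str | None = None
    genome_strand: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class ReadPair:
    """Both mates of one fragment, with Illumina mate suffixes stripped."""

    name: str
    seq1: str
    seq2: str


@dataclass(frozen=True)
class SamplePlan:
    """How many read pairs to draw and how.

    ``head`` takes the first pairs in file order (deterministic, the default);
    ``reservoir`` draws a uniform random subset reproducible for a fixed seed,
    for files with position-ordered biases.
    """

    n_requested: int = DEFAULT_SAMPLE_SIZE
    strategy: str = "head"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_requested < 1:
            raise ValueError("n_requested must be >= 1")
        if self.strategy not in ("head", "reservoir"):
            raise ValueError(f"unknown sampling strategy {self.strategy!r}")


def open_text(source: str | Path | IO) -> IO[str]:
    """Open ``source`` for text reading, transparently decompressing gzip.

    Gzip is recognised by its two magic bytes, so misnamed files still work.
    File-like objects are returned unchanged.
    """
    if not isinstance(source, (str, Path)):
        return source
    raw = open(source, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        import io as _io

        return _io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    import io as _io

    return _io.TextIOWrapper(raw, encoding="ascii")


def read_transcriptome(fasta_source: str | Path | IO) -> list[Transcript]:
    """Parse a transcriptome FASTA into :class:`Transcript` records.

    Sequences are uppercased; characters outside {A,C,G,T,N} become N (a
    warning reports how many).  The id is the first whitespace-delimited
    header token.  Duplicate ids and empty files are errors.
    """
    handle = open_text(fasta_source)
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    n_replaced = 0
    for record in SeqIO.parse(handle, "fasta"):
        if record.id in seen:
            raise DuplicateTranscriptError(
                f"duplicate transcript id {record.id!r} in FASTA"
            )
        seen.add(record.id)
        seq = str(record.seq).upper()
        cleaned = _NON_ACGTN.sub("N", seq)
        if cleaned != seq:
            n_replaced += sum(a != b for a, b in zip(seq, cleaned))
        transcripts.append(Transcript(id=record.id, sequence=cleaned))
    if not transcripts:
        raise ValueError("FASTA source contains no records")
    if n_replaced:
        log.warning("replaced %d non-ACGTN characters with N", n_replaced)
    return transcripts


def write_transcriptome(
    transcripts: Iterable[Transcript], path: str | Path, width: int = 60
) -> None:
    """Write transcripts as multi-line FASTA (sense strand, id-only headers)."""
    with open(path, "w") as out:
        for tx in transcripts:
            out.write(f">{tx.id}\n")
            for i in range(0, len(tx.sequence), width):
                out.write(tx.sequence[i : i + width] + "\n")


def strip_transcript_version(tid: str) -> str:
    """Drop a trailing '.<digits>' version, bridging Ensembl FASTA/GTF dialects."""
    return _VERSION_SUFFIX.sub("", tid)


def attach_gtf_strands(
    transcripts: list[Transcript], gtf_source: str | Path | IO
) -> list[Transcript]:
    """Fill ``genome_strand`` from a GTF's transcript/exon features.

    Matching strips a trailing version suffix on both sides.  Transcripts
    absent from the GTF keep ``genome_strand`` unset (their number is logged);
    none are removed.  An unparseable GTF line raises with its line number.
    """
    strand_of: dict[str, str] = {}
    handle = open_text(gtf_source)
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"GTF line {lineno}: expected 9 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            int(fields[3]), int(fields[4])
            feat = gffutils.feature.feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types
            raise GtfParseError(f"GTF line {lineno}: {exc}") from exc
        if feat.featuretype not in ("transcript", "exon"):
            continue
        if feat.strand not in ("+", "-"):
            continue
        tids = feat.attributes.get("transcript_id", [])
        if not tids:
            continue
        tid = strip_transcript_version(tids[0])
        prev = strand_of.setdefault(tid, feat.strand)
        if prev != feat.strand:
            log.warning(
                "transcript %s annotated on both strands in GTF; keeping %s",
                tid,
                prev,
            )
    out: list[Transcript] = []
    n_missing = 0
    for tx in transcripts:
        strand = strand_of.get(strip_transcript_version(tx.id))
        if strand is None:
            n_missing += 1
            out.append(tx)
        else:
            out.append(replace(tx, genome_strand=strand))
    if n_missing:
        log.warning("%d transcript(s) in FASTA but not in GTF", n_missing)
    return out


def strip_mate_suffix(title: str) -> str:
    """Reduce a FASTQ title line to the pair name.

    Takes the first whitespace token (dropping Casava 1.8 ' 1:N:0:...' tails)
    and strips a trailing '/1' or '/2' (older Illumina dialect).
    """
    name = title.split(None, 1)[0]
    if name.endswith(("/1", "/2")):
        name = name[:-2]
    return name


def _iter_pairs(
    fastq1_source, fastq2_source
) -> Iterator[tuple[int, str, str, str]]:
    """Yield (index, name, seq1, seq2), enforcing mate-name sync and counting."""
    h1, h2 = open_text(fastq1_source), open_text(fastq2_source)
    it1, it2 = FastqGeneralIterator(h1), FastqGeneralIterator(h2)
    sentinel = object()
    index = 0
    while True:
        try:
            rec1 = next(it1, sentinel)
        except ValueError as exc:
            raise FastqFormatError(f"file 1, record {index + 1}: {exc}") from exc
        try:
            rec2 = next(it2, sentinel)
        except ValueError as exc:
            raise FastqFormatError(f"file 2, record {index + 1}: {exc}") from exc
        if rec1 is sentinel and rec2 is sentinel:
            return
        if rec1 is sentinel or rec2 is sentinel:
            # drain the longer file so the error can state both counts
            n1, n2 = index, index
            if rec1 is not sentinel:
                n1 = index + 1 + sum(1 for _ in it1)
            if rec2 is not sentinel:
                n2 = index + 1 + sum(1 for _ in it2)
            raise PairSyncError(
                f"unequal record counts: file 1 has {n1}, file 2 has {n2}"
            )
        name1 = strip_mate_suffix(rec1[0])
        name2 = strip_mate_suffix(rec2[0])
        if name1 != name2:
            raise PairSyncError(
                f"mate name mismatch at pair {index + 1}: {name1!r} vs {name2!r}"
            )
        yield index, name1, rec1[1], rec2[1]
        index += 1


def sample_pairs(
    fastq1_source, fastq2_source, plan: SamplePlan | None = None
) -> list[ReadPair]:
    """Draw up to ``plan.n_requested`` synchronized read pairs from two FASTQs.

    Returns ``min(n_requested, pairs available)`` pairs.  ``head`` takes the
    first pairs and stops reading; ``reservoir`` scans both files fully and
    returns a uniform random subset (file order preserved, bit-reproducible
    for a fixed seed).  Mate-name mismatches and unequal record counts raise
    :class:`PairSyncError`.
    """
    plan = plan or SamplePlan()
    n = plan.n_requested
    pairs: list[ReadPair] = []
    if plan.strategy == "head":
        for index, name, s1, s2 in _iter_pairs(fastq1_source, fastq2_source):
            pairs.append(ReadPair(name, s1, s2))
            if len(pairs) >= n:
                break
    else:
        rng = random.Random(plan.seed)
        reservoir: list[tuple[int, ReadPair]] = []
        for index, name, s1, s2 in _iter_pairs(fastq1_source, fastq2_source):
            pair = ReadPair(name, s1, s2)
            if len(reservoir) < n:
                reservoir.append((index, pair))
            else:
                j = rng.randrange(index + 1)
                if j < n:
                    reservoir[j] = (index, pair)
        reservoir.sort(key=lambda t: t[0])
        pairs = [p for _, p in reservoir]
    if len(pairs) < n:
        log.warning(
            "fewer reads than requested: sampled %d of %d", len(pairs), n
        )
    return pairs


def write_fastq_pair(
    pairs: Iterable[ReadPair],
    path1: str | Path,
    path2: str | Path,
    quality_char: str = "I",
) -> None:
    """Write mates to two 4-line-record FASTQ files with constant quality."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{quality_char * len(p.seq1)}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{quality_char * len(p.seq2)}\n")
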