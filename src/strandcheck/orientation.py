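"""Classify read pairs into the FR/RF layout space and tally the outcomes.

FR means mate 1 carries the sense strand of the originating RNA (and mate 2
its complement); RF is the converse.  All decisions are made in transcript
(sense/antisense) space, so genome coordinates and a GTF are never required;
the RSeQC-style code strings are reporting sugar emitted only when the
transcript's genome strand is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .index import (
    AssignmentStatus,
    BatchAssignment,
    DEFAULT_MIN_VOTE_FRAC,
    KmerIndex,
    Orientation,
    ReadAssignment,
    assign_read,
    assign_reads,
)
from .io import ReadPair


class OrientationCall(str, Enum):
    """Per-pair layout call.

    FAILED covers pairs that mapped but whose orientation is undeterminable:
    a strand-ambiguous mate, discordant mates (both sense or both antisense),
    or mates assigned to disjoint transcript sets (likely chimeric pair).
    """

    FR = "FR"
    RF = "RF"
    FAILED = "FAILED"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class OrientationCounts:
    n_total: int = 0
    n_fr: int = 0
    n_rf: int = 0
    n_failed: int = 0
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        parts = self.n_fr + self.n_rf + self.n_failed + self.n_unmapped
        if parts != self.n_total:
            raise ValueError(
                f"category counts sum to {parts}, not n_total={self.n_total}"
            )


def _combine(
    a1: ReadAssignment, a2: ReadAssignment
) -> OrientationCall:
    """Decision table over the two mates' assignments."""
    s1, s2 = a1.status, a2.status
    A = AssignmentStatus.ASSIGNED
    if (
        s1 is AssignmentStatus.AMBIGUOUS_STRAND
        or s2 is AssignmentStatus.AMBIGUOUS_STRAND
    ):
        return OrientationCall.FAILED
    if s1 is A and s2 is A:
        if a1.orientation == a2.orientation:
            return OrientationCall.FAILED  # discordant: both sense/antisense
        if not (a1.transcripts & a2.transcripts):
            return OrientationCall.FAILED  # disjoint transcript sets
        return (
            OrientationCall.FR
            if a1.orientation is Orientation.SENSE
            else OrientationCall.RF
        )
    if s1 is A:
        return (
            OrientationCall.FR
            if a1.orientation is Orientation.SENSE
            else OrientationCall.RF
        )
    if s2 is A:
        return (
            OrientationCall.RF
            if a2.orientation is Orientation.SENSE
            else OrientationCall.FR
        )
    return OrientationCall.UNMAPPED


def classify_pair(
    pair: ReadPair,
    index: KmerIndex,
    min_vote_frac: float = DEFAULT_MIN_VOTE_FRAC,
) -> OrientationCall:
    """Classify one pair by assigning each mate independently.

    Single-mapped-mate pairs are still classified from that mate alone
    (mate-1 sense → FR, mate-1 antisense → RF; mate 2 the mirror), which
    keeps usable reads from libraries with a weak mate.
    """
    a1 = assign_read(pair.seq1, index, min_vote_frac)
    a2 = assign_read(pair.seq2, index, min_vote_frac)
    return _combine(a1, a2)


def classify_pairs(
    pairs: Sequence[ReadPair],
    index: KmerIndex,
    min_vote_frac: float = DEFAULT_MIN_VOTE_FRAC,
) -> list[OrientationCall]:
    """Vectorized classification of many pairs; equal to per-pair calls.

    Both mates of all pairs are assigned in batch.  The handful of pairs the
    batch path cannot resolve to single candidate transcripts fall back to
    the scalar decision, so the outcome is identical to ``classify_pair`` on
    every pair.
    """
    n = len(pairs)
    if n == 0:
        return []
    b1 = assign_reads([p.seq1 for p in pairs], index, min_vote_frac)
    b2 = assign_reads([p.seq2 for p in pairs], index, min_vote_frac)

    fr = np.zeros(n, dtype=bool)
    rf = np.zeros(n, dtype=bool)
    failed = np.zeros(n, dtype=bool)

    amb = (b1.status == 2) | (b2.status == 2)
    both = (b1.status == 1) & (b2.status == 1) & ~amb
    only1 = (b1.status == 1) & (b2.status != 1) & ~amb
    only2 = (b2.status == 1) & (b1.status != 1) & ~amb

    failed |= amb
    concord = both & (b1.orient != b2.orient)
    failed |= both & ~concord

    # disjointness: in the fast path each mate has one candidate transcript
    simple = concord & (b1.tx_single >= 0) & (b2.tx_single >= 0)
    same_tx = b1.tx_single == b2.tx_single
    fr |= simple & same_tx & (b1.orient == 0)
    rf |= simple & same_tx & (b1.orient == 1)
    failed |= simple & ~same_tx

    fr |= only1 & (b1.orient == 0)
    rf |= only1 & (b1.orient == 1)
    rf |= only2 & (b2.orient == 0)
    fr |= only2 & (b2.orient == 1)

    calls: list[OrientationCall] = [OrientationCall.UNMAPPED] * n
    for i in np.nonzero(fr)[0]:
        calls[i] = OrientationCall.FR
    for i in np.nonzero(rf)[0]:
        calls[i] = OrientationCall.RF
    for i in np.nonzero(failed)[0]:
        calls[i] = OrientationCall.FAILED
    for i in np.nonzero(concord & ~simple)[0]:  # need real set intersection
        calls[i] = _combine(
            _full_assignment(b1, int(i), pairs[int(i)].seq1, index, min_vote_frac),
            _full_assignment(b2, int(i), pairs[int(i)].seq2, index, min_vote_frac),
        )
    return calls


def _full_assignment(
    batch: BatchAssignment,
    i: int,
    seq: str,
    index: KmerIndex,
    min_vote_frac: float,
) -> ReadAssignment:
    """Materialize the full ReadAssignment for one batch row."""
    if i in batch.fallback:
        return batch.fallback[i]
    if batch.status[i] == 1 and batch.tx_single[i] >= 0:
        return ReadAssignment(
            status=AssignmentStatus.ASSIGNED,
            transcripts=frozenset((index.transcript_ids[int(batch.tx_single[i])],)),
            orientation=Orientation.SENSE if batch.orient[i] == 0 else Orientation.ANTISENSE,
            votes_sense=int(batch.votes_sense[i]),
            votes_antisense=int(batch.votes_antisense[i]),
        )
    return assign_read(seq, index, min_vote_frac)


def write_audit(
    pairs: Sequence[ReadPair],
    index: KmerIndex,
    path,
    min_vote_frac: float = DEFAULT_MIN_VOTE_FRAC,
) -> list[OrientationCall]:
    """Per-pair TSV audit dump for debugging: mate statuses, orientations, call.

    Off the hot path — intended for inspecting why specific pairs FAILED.
    Returns the calls so callers need not classify twice.
    """
    b1 = assign_reads([p.seq1 for p in pairs], index, min_vote_frac)
    b2 = assign_reads([p.seq2 for p in pairs], index, min_vote_frac)
    calls: list[OrientationCall] = []
    with open(path, "w") as out:
        out.write(
            "pair\tmate1_status\tmate1_orientation\t"
            "mate2_status\tmate2_orientation\tcall\n"
        )
        for i, pair in enumerate(pairs):
            a1 = _full_assignment(b1, i, pair.seq1, index, min_vote_frac)
            a2 = _full_assignment(b2, i, pair.seq2, index, min_vote_frac)
            call = _combine(a1, a2)
            calls.append(call)
            o1 = a1.orientation.value if a1.orientation else "."
            o2 = a2.orientation.value if a2.orientation else "."
            out.write(
                f"{pair.name}\t{a1.status.value}\t{o1}\t"
                f"{a2.status.value}\t{o2}\t{call.value}\n"
            )
    return calls


def tally(calls: Iterable[OrientationCall]) -> OrientationCounts:
    """Exact category counts; categories always sum to the total."""
    n_fr = n_rf = n_failed = n_unmapped = 0
    for c in calls:
        if c is OrientationCall.FR:
            n_fr += 1
        elif c is OrientationCall.RF:
            n_rf += 1
        elif c is OrientationCall.FAILED:
            n_failed += 1
        else:
            n_unmapped += 1
    return OrientationCounts(
        n_total=n_fr + n_rf + n_failed + n_unmapped,
        n_fr=n_fr,
        n_rf=n_rf,
        n_failed=n_failed,
        n_unmapped=n_unmapped,
    )


# (mate-1 code, mate-2 code) per (layout, genome strand) — RSeQC notation
_RSEQC = {
    (OrientationCall.FR, "+"): "1++,2+-",
    (OrientationCall.FR, "-"): "1--,2-+",
    (OrientationCall.RF, "+"): "1+-,2++",
    (OrientationCall.RF, "-"): "1-+,2--",
}

FR_CODE_SUMMARY = "1++,1--,2+-,2-+"
RF_CODE_SUMMARY = "1+-,1-+,2++,2--"


def rseqc_code(call: OrientationCall, genome_strand: str | None) -> str | None:
    """RSeQC-style (mate, read strand, feature strand) code for one call.

    Requires the assigned transcript's genome strand (from a GTF); returns
    None when it is unknown or the call carries no layout — the call is
    still counted either way.
    """
    if genome_strand not in ("+", "-"):
        return None
    return _RSEQC.get((call, genome_strand))
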