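"""Strand-aware k-mer voting index over a transcriptome.

Only the *sense* k-mers of the transcripts are stored.  A read is probed in
both orientations: the count of its forward k-mers present in the table is the
sense vote, the count for its reverse complement the antisense vote.  The
winning orientation (if decisive) gives the read's implied strand relative to
the mRNA, which is all the downstream strandedness statistic needs — no
alignment, abundances or genome coordinates.

K-mers are packed 2 bits/base into uint64 codes and kept in a sorted array;
membership tests are binary searches (numpy ``searchsorted``), which makes
classifying a 200,000-pair sample a matter of seconds on one CPU.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from numba import njit

from .io import Transcript

log = logging.getLogger("strandcheck")

INDEX_FORMAT_VERSION = "strandcheck-index-1"
DEFAULT_K = 31
DEFAULT_MIN_VOTE_FRAC = 0.25

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class IndexLoadError(ValueError):
    """Index artifact missing, corrupt, or of an incompatible version."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_RC_TABLE)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes_2d(bases: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit packing of every length-k window of each row.

    ``bases`` is (n, L) uint8.  Returns (codes, valid) of shape (n, L-k+1):
    ``valid`` is False for windows containing a non-ACGT base, whose codes are
    meaningless and must be ignored by callers.
    """
    n, L = bases.shape
    m = L - k + 1
    if m <= 0:
        return (np.zeros((n, 0), np.uint64), np.zeros((n, 0), bool))
    mask = np.uint64((1 << (2 * k)) - 1) if 2 * k < 64 else np.uint64(2**64 - 1)
    # work transposed so every per-position slice is contiguous
    bT = np.ascontiguousarray(bases.T).astype(np.uint64)
    badT = bT == 4
    np.copyto(bT, 0, where=badT)
    codesT = np.zeros((m, n), dtype=np.uint64)
    acc = np.zeros(n, dtype=np.uint64)
    run = np.zeros(n, dtype=np.int64)  # clean-base run length ending here
    validT = np.zeros((m, n), dtype=bool)
    two = np.uint64(2)
    for i in range(L):
        acc = ((acc << two) | bT[i]) & mask
        run = np.where(badT[i], 0, run + 1)
        if i >= k - 1:
            codesT[i - k + 1] = acc
            validT[i - k + 1] = run >= k
    return np.ascontiguousarray(codesT.T), np.ascontiguousarray(validT.T)


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes and validity of all forward k-mer windows of one sequence.

    Vectorized over window starts (k shift-or passes), so long sequences
    (whole transcripts) pack in milliseconds.
    """
    b = encode_bases(seq)
    L = len(b)
    m = L - k + 1
    if m <= 0:
        return np.zeros(0, np.uint64), np.zeros(0, bool)
    bad = b == 4
    clean = np.where(bad, 0, b).astype(np.uint64)
    codes = np.zeros(m, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        codes = (codes << two) | clean[j : j + m]
    nbad = np.cumsum(bad)
    in_window = nbad[k - 1 :].copy()
    in_window[1:] -= nbad[: m - 1]
    return codes, in_window == 0


class Orientation(str, Enum):
    SENSE = "SENSE"
    ANTISENSE = "ANTISENSE"


class AssignmentStatus(str, Enum):
    ASSIGNED = "ASSIGNED"
    UNMAPPED = "UNMAPPED"
    AMBIGUOUS_STRAND = "AMBIGUOUS_STRAND"


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of probing one read against the index.

    ``transcripts`` is the intersection of candidate id-sets over the winning
    orientation's matching k-mers; when that intersection is empty (e.g. a
    junction read spanning isoforms) it falls back to their union and
    ``multi_transcript`` is set.  Orientation is decided purely by vote
    counts, so it remains trustworthy in the fallback case.
    """

    status: AssignmentStatus
    transcripts: frozenset[str] = frozenset()
    orientation: Orientation | None = None
    votes_sense: int = 0
    votes_antisense: int = 0
    multi_transcript: bool = False


class _TableView(Mapping):
    """Read-only mapping from k-mer string to set of transcript ids.

    A decoded view over the packed arrays, so the dict-of-strings never has
    to materialize for large indexes.
    """

    _BASES = "ACGT"

    def __init__(self, index: "KmerIndex") -> None:
        self._idx = index

    def _decode(self, code: int) -> str:
        k = self._idx.k
        out = []
        for shift in range(2 * (k - 1), -1, -2):
            out.append(self._BASES[(code >> shift) & 3])
        return "".join(out)

    def __len__(self) -> int:
        return len(self._idx._codes)

    def __iter__(self) -> Iterator[str]:
        for code in self._idx._codes:
            yield self._decode(int(code))

    def __getitem__(self, kmer: str) -> frozenset[str]:
        idx = self._idx
        if len(kmer) != idx.k:
            raise KeyError(kmer)
        codes, valid = kmer_codes(kmer, idx.k)
        if not valid[0]:
            raise KeyError(kmer)
        pos = int(np.searchsorted(idx._codes, codes[0]))
        if pos >= len(idx._codes) or idx._codes[pos] != codes[0]:
            raise KeyError(kmer)
        return idx._ids_at(pos)


@dataclass
class KmerIndex:
    """Sorted-array exact k-mer index with per-k-mer transcript id sets.

    ``_codes`` holds every distinct sense k-mer (packed uint64, sorted);
    ``_tx_of`` holds, aligned with it, either the single owning transcript's
    integer index or -1 for k-mers shared by several transcripts, whose id
    lists live in ``_multi``.
    """

    k: int
    transcript_ids: list[str]
    _codes: np.ndarray = field(repr=False)
    _tx_of: np.ndarray = field(repr=False)
    _multi: dict[int, tuple[int, ...]] = field(repr=False, default_factory=dict)

    _BUCKET_BITS = 21  # ~2M buckets; avg occupancy << 1 for typical indexes

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def _ensure_buckets(self) -> None:
        """Build the top-bits bucket directory that accelerates membership.

        Probing then costs one offset fetch plus a scan bounded by the
        largest bucket, instead of a full binary search per k-mer.  Derived
        from ``_codes``; never serialized.
        """
        if getattr(self, "_bucket_offsets", None) is not None:
            return
        bits = min(self._BUCKET_BITS, 2 * self.k)
        self._bucket_shift = np.uint64(2 * self.k - bits)
        buckets = (self._codes >> self._bucket_shift).astype(np.int64)
        counts = np.bincount(buckets, minlength=(1 << bits))
        self._bucket_max = int(counts.max()) if len(counts) else 0
        offsets = np.zeros(len(counts) + 1, dtype=np.int64)
        np.cumsum(counts, out=offsets[1:])
        self._bucket_offsets = offsets

    def lookup_flat(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(hit mask, position in ``_codes``) for a flat uint64 code array.

        Falls back to plain binary search when the bucket directory is
        degenerate (a very repetitive transcriptome piling codes into few
        buckets).
        """
        codes = self._codes
        size = len(codes)
        if size == 0 or len(queries) == 0:
            return np.zeros(len(queries), bool), np.zeros(len(queries), np.int64)
        self._ensure_buckets()
        if self._bucket_max > 64:
            pos = np.searchsorted(codes, queries)
            pos_c = np.minimum(pos, size - 1)
            return codes[pos_c] == queries, pos_c
        bkt = (queries >> self._bucket_shift).astype(np.int64)
        cur = self._bucket_offsets[bkt]
        hi = self._bucket_offsets[bkt + 1]
        found = np.zeros(len(queries), dtype=bool)
        pos = np.zeros(len(queries), dtype=np.int64)
        # walk each non-empty bucket, shedding resolved queries every step
        alive = np.nonzero(cur < hi)[0]
        while alive.size:
            c = cur[alive]
            match = codes[c] == queries[alive]
            hit_rows = alive[match]
            found[hit_rows] = True
            pos[hit_rows] = c[match]
            alive = alive[~match]
            cur[alive] += 1
            alive = alive[cur[alive] < hi[alive]]
        return found, pos

    @property
    def n_kmers(self) -> int:
        return len(self._codes)

    @property
    def table(self) -> Mapping:
        return _TableView(self)

    def _ids_at(self, pos: int) -> frozenset[str]:
        t = int(self._tx_of[pos])
        if t >= 0:
            return frozenset((self.transcript_ids[t],))
        members = self._multi[int(self._codes[pos])]
        return frozenset(self.transcript_ids[i] for i in members)

    # ---- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a versioned .npz artifact reusable across runs on one species."""
        multi_codes = np.array(sorted(self._multi), dtype=np.uint64)
        multi_json = json.dumps(
            [list(self._multi[int(c)]) for c in multi_codes]
        )
        with open(path, "wb") as fh:  # keep the caller's exact filename
            np.savez_compressed(
                fh,
                format_version=np.array(INDEX_FORMAT_VERSION),
                k=np.array(self.k),
                codes=self._codes,
                tx_of=self._tx_of,
                transcript_ids=np.array(self.transcript_ids),
                multi_codes=multi_codes,
                multi_members=np.array(multi_json),
            )

    @classmethod
    def load(cls, path: str | Path) -> "KmerIndex":
        try:
            with np.load(path, allow_pickle=False) as data:
                version = str(data["format_version"])
                if version != INDEX_FORMAT_VERSION:
                    raise IndexLoadError(
                        f"index {path} has format {version!r}, expected "
                        f"{INDEX_FORMAT_VERSION!r}; rebuild it with build-index"
                    )
                multi_codes = data["multi_codes"]
                members = json.loads(str(data["multi_members"]))
                return cls(
                    k=int(data["k"]),
                    transcript_ids=[str(s) for s in data["transcript_ids"]],
                    _codes=data["codes"],
                    _tx_of=data["tx_of"],
                    _multi={
                        int(c): tuple(m) for c, m in zip(multi_codes, members)
                    },
                )
        except IndexLoadError:
            raise
        except Exception as exc:
            raise IndexLoadError(
                f"cannot load index from {path}: {exc}; rebuild it with build-index"
            ) from exc


def build_index(transcripts: Sequence[Transcript], k: int = DEFAULT_K) -> KmerIndex:
    """Index every sense k-mer of every transcript.

    k must be odd (no palindromic self-complements) and at most 63 (2 bits
    per base in a 64-bit word); values below ~11 are only sensible for toy
    references.  K-mers containing N are skipped; transcripts shorter than k
    contribute nothing (their count is logged).  Raises if no transcript
    reaches length k.
    """
    if k % 2 == 0 or not (3 <= k <= 63):
        raise ValueError(f"k must be odd and in [3, 63], got {k}")
    if k < 11:
        log.warning("k=%d is very small; expect spurious matches on real data", k)
    code_chunks: list[np.ndarray] = []
    tx_chunks: list[np.ndarray] = []
    n_short = 0
    for tx_idx, tx in enumerate(transcripts):
        if len(tx.sequence) < k:
            n_short += 1
            continue
        codes, valid = kmer_codes(tx.sequence, k)
        codes = codes[valid]
        code_chunks.append(codes)
        tx_chunks.append(np.full(len(codes), tx_idx, dtype=np.int64))
    if not code_chunks:
        raise ValueError(f"no transcript reaches the k-mer length k={k}")
    if n_short:
        log.warning("%d transcript(s) shorter than k=%d contribute no k-mers", n_short, k)

    codes = np.concatenate(code_chunks)
    txs = np.concatenate(tx_chunks)
    # drop duplicate (code, transcript) pairs, then group codes
    order = np.lexsort((txs, codes))
    codes, txs = codes[order], txs[order]
    keep = np.ones(len(codes), dtype=bool)
    keep[1:] = (codes[1:] != codes[:-1]) | (txs[1:] != txs[:-1])
    codes, txs = codes[keep], txs[keep]

    uniq_codes, start, counts = np.unique(
        codes, return_index=True, return_counts=True
    )
    tx_of = np.where(counts == 1, txs[start], -1).astype(np.int64)
    multi: dict[int, tuple[int, ...]] = {}
    for pos in np.nonzero(counts > 1)[0]:
        s = start[pos]
        multi[int(uniq_codes[pos])] = tuple(
            int(t) for t in txs[s : s + counts[pos]]
        )
    return KmerIndex(
        k=k,
        transcript_ids=[tx.id for tx in transcripts],
        _codes=uniq_codes,
        _tx_of=tx_of,
        _multi=multi,
    )


def _lookup(index: KmerIndex, flat_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(hit mask, position in index._codes) for a flat array of k-mer codes."""
    return index.lookup_flat(flat_codes)


def _decide(
    votes_s: int, votes_a: int, m: int, min_vote_frac: float
) -> tuple[AssignmentStatus, Orientation | None]:
    """Vote rule shared by the scalar and batch paths.

    Threshold is ``min_vote_frac`` of ALL k-mer windows in the read (N-laden
    windows count toward the denominator: an unreadable read should not be
    easier to assign).  Near-ties (<= 1 vote apart) with both orientations
    above threshold are strand-ambiguous, not assigned.
    """
    thr = min_vote_frac * m
    v, lo = max(votes_s, votes_a), min(votes_s, votes_a)
    if m == 0 or v < thr:
        return AssignmentStatus.UNMAPPED, None
    if lo >= thr and v - lo <= 1:
        return AssignmentStatus.AMBIGUOUS_STRAND, None
    if v == lo:  # tie without both passing threshold cannot happen (v==lo>=thr)
        return AssignmentStatus.AMBIGUOUS_STRAND, None
    orient = Orientation.SENSE if votes_s > votes_a else Orientation.ANTISENSE
    return AssignmentStatus.ASSIGNED, orient


def assign_read(
    seq: str, index: KmerIndex, min_vote_frac: float = DEFAULT_MIN_VOTE_FRAC
) -> ReadAssignment:
    """Assign one read to transcripts and an implied orientation.

    Reference (scalar) implementation; ``assign_reads`` is the vectorized
    equivalent used by the pipeline.  Reads shorter than k are UNMAPPED with
    zero votes rather than an error.
    """
    k = index.k
    if len(seq) < k:
        return ReadAssignment(status=AssignmentStatus.UNMAPPED)
    m = len(seq) - k + 1
    fwd_codes, fwd_valid = kmer_codes(seq, k)
    rc_codes, rc_valid = kmer_codes(revcomp(seq), k)
    fhit, fpos = _lookup(index, fwd_codes)
    rhit, rpos = _lookup(index, rc_codes)
    fhit &= fwd_valid
    rhit &= rc_valid
    votes_s, votes_a = int(fhit.sum()), int(rhit.sum())
    status, orient = _decide(votes_s, votes_a, m, min_vote_frac)
    if status is not AssignmentStatus.ASSIGNED:
        return ReadAssignment(
            status=status, votes_sense=votes_s, votes_antisense=votes_a
        )
    hit, pos = (fhit, fpos) if orient is Orientation.SENSE else (rhit, rpos)
    id_sets = [index._ids_at(int(p)) for p in pos[hit]]
    inter = frozenset.intersection(*id_sets)
    multi = False
    if not inter:
        inter = frozenset.union(*id_sets)
        multi = True
    return ReadAssignment(
        status=AssignmentStatus.ASSIGNED,
        transcripts=inter,
        orientation=orient,
        votes_sense=votes_s,
        votes_antisense=votes_a,
        multi_transcript=multi,
    )


@njit(cache=True)
def _vote_kernel(
    bases, k, codes, tx_of, offsets, shift, votes_s, votes_a, tx_lo, tx_hi, tx_multi
):  # pragma: no cover - exercised via assign_reads
    """Count sense/antisense k-mer votes for every read of one length group.

    Rolls both the forward code and its reverse complement across each read,
    probing the bucket directory per valid window.  Tracks, per orientation,
    the min/max owning-transcript index over hits and whether any hit k-mer
    is shared by several transcripts, so the caller can tell single-candidate
    reads from ones needing full id-set resolution.
    """
    n, L = bases.shape
    kmask = (np.uint64(1) << np.uint64(2 * k)) - np.uint64(1)
    top_shift = np.uint64(2 * (k - 1))
    big = np.int64(2**62)
    for r in range(n):
        acc = np.uint64(0)
        rc = np.uint64(0)
        run = 0
        vs = 0
        va = 0
        for o in range(2):
            tx_lo[r, o] = big
            tx_hi[r, o] = -1
            tx_multi[r, o] = False
        for i in range(L):
            b = bases[r, i]
            if b > 3:
                run = 0
                b = np.uint8(0)
            else:
                run += 1
            acc = ((acc << np.uint64(2)) | np.uint64(b)) & kmask
            rc = (rc >> np.uint64(2)) | (np.uint64(3 - b) << top_shift)
            if i >= k - 1 and run >= k:
                bkt = acc >> shift
                for j in range(offsets[bkt], offsets[bkt + 1]):
                    if codes[j] == acc:
                        vs += 1
                        t = tx_of[j]
                        if t < 0:
                            tx_multi[r, 0] = True
                        else:
                            if t < tx_lo[r, 0]:
                                tx_lo[r, 0] = t
                            if t > tx_hi[r, 0]:
                                tx_hi[r, 0] = t
                        break
                bkt = rc >> shift
                for j in range(offsets[bkt], offsets[bkt + 1]):
                    if codes[j] == rc:
                        va += 1
                        t = tx_of[j]
                        if t < 0:
                            tx_multi[r, 1] = True
                        else:
                            if t < tx_lo[r, 1]:
                                tx_lo[r, 1] = t
                            if t > tx_hi[r, 1]:
                                tx_hi[r, 1] = t
                        break
        votes_s[r] = vs
        votes_a[r] = va


@dataclass
class BatchAssignment:
    """Vectorized per-read assignment results for equal-work downstream code.

    ``status``: 0 UNMAPPED, 1 ASSIGNED, 2 AMBIGUOUS_STRAND.
    ``orient``: 0 SENSE, 1 ANTISENSE, -1 undefined.
    ``tx_single``: index of the unique candidate transcript, or -1 when the
    read has no single candidate (shared k-mers or multiple ids) — those
    reads carry a full :class:`ReadAssignment` in ``fallback``.
    """

    status: np.ndarray
    orient: np.ndarray
    tx_single: np.ndarray
    votes_sense: np.ndarray
    votes_antisense: np.ndarray
    fallback: dict[int, ReadAssignment]


def assign_reads(
    seqs: Sequence[str],
    index: KmerIndex,
    min_vote_frac: float = DEFAULT_MIN_VOTE_FRAC,
) -> BatchAssignment:
    """Vectorized :func:`assign_read` over many reads.

    Reads are grouped by length and processed as 2-D code arrays; the rare
    reads whose candidate transcripts cannot be resolved to a single id in
    vector form (multi-mapping k-mers, disagreeing ids) are re-assigned via
    the scalar reference path, so results are always identical to it.
    """
    n = len(seqs)
    status = np.zeros(n, dtype=np.int8)
    orient = np.full(n, -1, dtype=np.int8)
    tx_single = np.full(n, -1, dtype=np.int64)
    votes_s_out = np.zeros(n, dtype=np.int32)
    votes_a_out = np.zeros(n, dtype=np.int32)
    fallback: dict[int, ReadAssignment] = {}

    k = index.k
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)

    index._ensure_buckets()
    frac = min_vote_frac
    for L, rows in by_len.items():
        if L < k:
            continue  # UNMAPPED, zero votes — already the default
        m = L - k + 1
        idx_rows = np.array(rows)
        buf = np.frombuffer(
            "".join(seqs[i] for i in rows).encode("ascii"), dtype=np.uint8
        ).reshape(len(rows), L)
        bases = _ENCODE[buf]

        nr = len(rows)
        vs = np.zeros(nr, dtype=np.int64)
        va = np.zeros(nr, dtype=np.int64)
        tx_lo = np.zeros((nr, 2), dtype=np.int64)
        tx_hi = np.zeros((nr, 2), dtype=np.int64)
        tx_multi = np.zeros((nr, 2), dtype=np.bool_)
        _vote_kernel(
            bases,
            k,
            index._codes,
            index._tx_of,
            index._bucket_offsets,
            index._bucket_shift,
            vs,
            va,
            tx_lo,
            tx_hi,
            tx_multi,
        )
        votes_s_out[idx_rows] = vs
        votes_a_out[idx_rows] = va

        thr = frac * m
        v = np.maximum(vs, va)
        lo = np.minimum(vs, va)
        unmapped = v < thr
        ambiguous = ~unmapped & (lo >= thr) & (v - lo <= 1)
        assigned = ~unmapped & ~ambiguous & (v > lo)
        ambiguous |= ~unmapped & ~assigned & ~ambiguous  # exact ties
        status[idx_rows[assigned]] = 1
        status[idx_rows[ambiguous]] = 2

        sense_wins = vs > va
        orient[idx_rows[assigned & sense_wins]] = 0
        orient[idx_rows[assigned & ~sense_wins]] = 1

        # resolve the candidate transcript for assigned reads
        win = np.where(sense_wins, 0, 1)
        r_idx = np.arange(nr)
        tmin = tx_lo[r_idx, win]
        tmax = tx_hi[r_idx, win]
        wmulti = tx_multi[r_idx, win]
        single = assigned & ~wmulti & (tmin == tmax) & (tmax >= 0)
        tx_single[idx_rows[single]] = tmin[single]
        needs_scalar = assigned & ~single
        for r in np.nonzero(needs_scalar)[0]:
            gi = rows[r]
            fallback[gi] = assign_read(seqs[gi], index, min_vote_frac)
    return BatchAssignment(
        status=status,
        orient=orient,
        tx_single=tx_single,
        votes_sense=votes_s_out,
        votes_antisense=votes_a_out,
        fallback=fallback,
    )
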