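"""End-to-end orchestration: transcriptome → index → sample → classify → report.

This is the importable equivalent of the ``check-strandedness`` command; the
CLI is a thin flag-parsing layer over :func:`check_strandedness`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import index as _index
from . import io as _io
from . import orientation as _orientation
from . import stats as _stats

log = logging.getLogger("strandcheck")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one strandedness check needs.

    ``gtf`` is optional: orientation is decided in transcript space, and the
    GTF only enables RSeQC-style code strings in logs.  ``index_path`` reuses
    a saved index artifact and skips the (re)build.
    """

    reads_1: str | Path
    reads_2: str | Path
    transcripts: str | Path | None = None
    gtf: str | Path | None = None
    index_path: str | Path | None = None
    n_reads: int = _io.DEFAULT_SAMPLE_SIZE
    kmer_size: int = _index.DEFAULT_K
    min_vote_frac: float = _index.DEFAULT_MIN_VOTE_FRAC
    thresholds: _stats.Thresholds = field(default_factory=_stats.Thresholds)
    denominator: str = "determined"
    sample_strategy: str = "head"
    seed: int = 0
    out_prefix: str | Path | None = None
    audit_path: str | Path | None = None  # per-pair TSV dump, off by default

    def __post_init__(self) -> None:
        if self.transcripts is None and self.index_path is None:
            raise ValueError("need a transcriptome FASTA or a saved index")


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            log.info("stage %-16s %.2fs", name, time.perf_counter() - self.t0)

    return _Timer()


def run_on_pairs(
    pairs: Sequence[_io.ReadPair],
    index: _index.KmerIndex,
    min_vote_frac: float = _index.DEFAULT_MIN_VOTE_FRAC,
    thresholds: _stats.Thresholds | None = None,
    denominator: str = "determined",
) -> _stats.StrandednessReport:
    """Classify already-sampled pairs against a built index and report."""
    calls = _orientation.classify_pairs(pairs, index, min_vote_frac)
    counts = _orientation.tally(calls)
    return _stats.build_report(counts, thresholds, denominator=denominator)


def check_strandedness(config: RunConfig) -> _stats.StrandednessReport:
    """Run the full check and (optionally) write report files.

    Stages: load transcriptome → attach GTF strands → build or load index →
    sample pairs → classify → tally → decide.  Writes ``<prefix>.json`` and
    ``<prefix>.tsv`` when ``out_prefix`` is set.  Raises
    :class:`PipelineError` with a stage label on any failure; an
    INCONCLUSIVE verdict is a successful run.
    """
    transcripts = None
    if config.transcripts is not None:
        with _stage("load_transcriptome"):
            transcripts = _io.read_transcriptome(config.transcripts)
            log.info("loaded %d transcripts", len(transcripts))
        if config.gtf is not None:
            with _stage("attach_gtf"):
                transcripts = _io.attach_gtf_strands(transcripts, config.gtf)

    if config.index_path is not None and Path(config.index_path).exists():
        with _stage("load_index"):
            idx = _index.KmerIndex.load(config.index_path)
            if idx.k != config.kmer_size:
                log.warning(
                    "index stores k=%d; ignoring requested k=%d",
                    idx.k,
                    config.kmer_size,
                )
    else:
        if transcripts is None:
            raise PipelineError(
                f"stage 'load_index': index {config.index_path} not found and "
                "no transcriptome FASTA given"
            )
        with _stage("build_index"):
            idx = _index.build_index(transcripts, k=config.kmer_size)
            log.info("indexed %d k-mers (k=%d)", idx.n_kmers, idx.k)
        if config.index_path is not None:
            with _stage("save_index"):
                idx.save(config.index_path)

    with _stage("sample_pairs"):
        plan = _io.SamplePlan(
            n_requested=config.n_reads,
            strategy=config.sample_strategy,
            seed=config.seed,
        )
        pairs = _io.sample_pairs(config.reads_1, config.reads_2, plan)
        log.info("sampled %d read pairs", len(pairs))

    with _stage("classify"):
        if config.audit_path is not None:
            calls = _orientation.write_audit(
                pairs, idx, config.audit_path, config.min_vote_frac
            )
        else:
            calls = _orientation.classify_pairs(pairs, idx, config.min_vote_frac)
        counts = _orientation.tally(calls)
        log.info(
            "assigned: FR=%d RF=%d failed=%d unmapped=%d",
            counts.n_fr,
            counts.n_rf,
            counts.n_failed,
            counts.n_unmapped,
        )

    with _stage("report"):
        report = _stats.build_report(
            counts, config.thresholds, denominator=config.denominator
        )

    if config.out_prefix is not None:
        prefix = Path(config.out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        Path(str(prefix) + ".json").write_text(report.to_json() + "\n")
        Path(str(prefix) + ".tsv").write_text(report.to_tsv())
    return report
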