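"""Stranded proportion, decision thresholds, and the final QC report.

The core statistic is the *stranded proportion*: the larger of the FR and RF
fractions among read pairs whose orientation could be determined.  Fully
strand-specific libraries sit near 1, unstranded libraries near 0.5.  A
library is called stranded when the proportion exceeds 0.9 and unstranded
when it falls below 0.6; anything between is inconclusive and usually means
trouble (genomic DNA carry-over, incompletely depleted small RNAs, mixed
protocols).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

from statsmodels.stats.proportion import proportion_confint

from .orientation import OrientationCounts


class UndefinedProportionError(ValueError):
    """No determinable read pairs: the stranded proportion does not exist."""


class Verdict(str, Enum):
    FR_STRANDED = "FR_STRANDED"
    RF_STRANDED = "RF_STRANDED"
    UNSTRANDED = "UNSTRANDED"
    INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class Thresholds:
    """Decision cutoffs.

    ``stranded_min``/``unstranded_max`` are strict bounds: a proportion must
    exceed 0.9 to call a stranded layout and fall below 0.6 to call
    unstranded; values at or between the cutoffs are inconclusive.
    ``low_align_warn`` flags runs where too few sampled reads hit the
    transcriptome for the verdict to mean much, and ``min_determined_pairs``
    flags thin evidence (high sampling variance at small counts).
    """

    stranded_min: float = 0.9
    unstranded_max: float = 0.6
    low_align_warn: float = 0.1
    min_determined_pairs: int = 1000

    def __post_init__(self) -> None:
        if not (0.5 < self.unstranded_max < self.stranded_min <= 1.0):
            raise ValueError(
                "need 0.5 < unstranded_max < stranded_min <= 1, got "
                f"{self.unstranded_max} / {self.stranded_min}"
            )


@dataclass(frozen=True)
class StrandednessReport:
    counts: OrientationCounts
    frac_fr: float
    frac_rf: float
    failed_frac: float
    aligned_frac: float
    stranded_proportion: float
    verdict: Verdict
    ci_low: float
    ci_high: float
    warnings: list[str] = field(default_factory=list)

    @property
    def percent_stranded(self) -> float:
        return 100.0 * self.stranded_proportion

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "n_sampled": c.n_total,
            "n_unmapped": c.n_unmapped,
            "n_failed": c.n_failed,
            "n_fr": c.n_fr,
            "n_rf": c.n_rf,
            "aligned_frac": self.aligned_frac,
            "stranded_proportion": self.stranded_proportion,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "verdict": self.verdict.value,
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        d = self.to_dict()
        d["warnings"] = ";".join(self.warnings)
        keys = list(d)
        fmt = lambda v: f"{v:.6f}" if isinstance(v, float) else str(v)
        return (
            "\t".join(keys) + "\n" + "\t".join(fmt(d[k]) for k in keys) + "\n"
        )


def stranded_proportion(counts: OrientationCounts) -> float:
    """max(n_fr, n_rf) / (n_fr + n_rf); undefined without determinable pairs."""
    det = counts.n_fr + counts.n_rf
    if det == 0:
        raise UndefinedProportionError(
            "no read pair could be assigned an FR or RF orientation "
            "(nothing mapped, or everything was ambiguous)"
        )
    return max(counts.n_fr, counts.n_rf) / det


def binomial_interval(
    n_major: int, n_determined: int, level: float = 0.99
) -> tuple[float, float]:
    """Two-sided Wilson score interval for the true stranded proportion.

    Reporting only — the verdict never consults it.
    """
    if n_determined <= 0:
        raise ValueError("n_determined must be positive")
    if not 0 <= n_major <= n_determined:
        raise ValueError("need 0 <= n_major <= n_determined")
    lo, hi = proportion_confint(
        n_major, n_determined, alpha=1.0 - level, method="wilson"
    )
    return float(lo), float(hi)


def build_report(
    counts: OrientationCounts,
    thresholds: Thresholds | None = None,
    denominator: str = "determined",
    ci_level: float = 0.99,
) -> StrandednessReport:
    """Turn orientation counts into the final report.

    ``denominator`` selects what the 90%/60% cutoffs are fractions *of*:
    "determined" (default) uses orientable pairs only (n_fr + n_rf), keeping
    mapping quality from masquerading as unstrandedness; "total" uses every
    sampled pair.
    """
    thresholds = thresholds or Thresholds()
    if denominator not in ("determined", "total"):
        raise ValueError(f"unknown denominator {denominator!r}")
    n_det = counts.n_fr + counts.n_rf
    if n_det == 0:
        raise UndefinedProportionError(
            "no read pair could be assigned an FR or RF orientation "
            "(nothing mapped, or everything was ambiguous)"
        )
    frac_fr = counts.n_fr / n_det
    frac_rf = counts.n_rf / n_det
    n_major = max(counts.n_fr, counts.n_rf)
    denom = n_det if denominator == "determined" else counts.n_total
    proportion = n_major / denom
    failed_frac = counts.n_failed / counts.n_total if counts.n_total else 0.0
    aligned_frac = (
        (counts.n_total - counts.n_unmapped) / counts.n_total
        if counts.n_total
        else 0.0
    )
    ci_low, ci_high = binomial_interval(n_major, denom, level=ci_level)

    warnings: list[str] = []
    if proportion > thresholds.stranded_min:
        verdict = (
            Verdict.FR_STRANDED if counts.n_fr >= counts.n_rf else Verdict.RF_STRANDED
        )
    elif proportion < thresholds.unstranded_max:
        verdict = Verdict.UNSTRANDED
    else:
        verdict = Verdict.INCONCLUSIVE
        warnings.append(
            "stranded proportion between the unstranded and stranded cutoffs; "
            "possible contamination (e.g. genomic DNA carry-over or "
            "undepleted small RNAs) or a mixed library"
        )
    if aligned_frac < thresholds.low_align_warn:
        warnings.append(
            f"only {aligned_frac:.1%} of sampled pairs aligned to the "
            "transcriptome; verdict unreliable (wrong or incomplete reference?)"
        )
    if n_det < thresholds.min_determined_pairs:
        warnings.append(
            f"only {n_det} orientable pairs "
            f"(< {thresholds.min_determined_pairs}); estimate is noisy"
        )
    if failed_frac > 0.2:
        warnings.append(
            f"{failed_frac:.1%} of pairs mapped but failed orientation; "
            "check for chimeric reads or an inappropriate reference"
        )
    return StrandednessReport(
        counts=counts,
        frac_fr=frac_fr,
        frac_rf=frac_rf,
        failed_frac=failed_frac,
        aligned_frac=aligned_frac,
        stranded_proportion=proportion,
        verdict=verdict,
        ci_low=ci_low,
        ci_high=ci_high,
        warnings=warnings,
    )


def format_report_text(report: StrandednessReport) -> str:
    """Human-readable report block (fractions to 4 decimals)."""
    c = report.counts
    lines = [
        f"read pairs sampled        {c.n_total}",
        f"unmapped pairs            {c.n_unmapped}",
        f"failed orientation        {c.n_failed}",
        f"FR pairs                  {c.n_fr}",
        f"RF pairs                  {c.n_rf}",
        f"aligned fraction          {report.aligned_frac:.4f}",
        f"FR fraction (determined)  {report.frac_fr:.4f}",
        f"RF fraction (determined)  {report.frac_rf:.4f}",
        f"stranded proportion       {report.stranded_proportion:.4f} "
        f"(99% CI {report.ci_low:.4f}-{report.ci_high:.4f})",
        f"verdict: {report.verdict.value}",
    ]
    for w in report.warnings:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines) + "\n"
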