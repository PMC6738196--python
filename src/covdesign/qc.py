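"""Coverage and variant QC against a solved design.

Takes per-base depth tables (samtools-depth TSV or BED) and candidate
variant observations (VCF with AD/DP, or a plain TSV), checks them
against a solved (depth, threshold) design, and assembles the reporting
fields a diagnostic assay should disclose: LOD, overall error, required
depth and threshold, the fraction of targeted bases at the required
depth, the intervals falling below it, and per-variant read support
with a call status.

Coordinates are 1-based inclusive internally (the samtools-depth
convention); BED input/output converts at the boundary.

Per-variant thresholds are re-solved at each observation's own depth
via :func:`covdesign.design.min_variant_reads`, because observed depths
vary position to position; the design depth acts only as the
insufficient-depth gate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
import pysam

from .design import DetectionDesign, ThresholdDecision, min_variant_reads

__all__ = [
    "ParseError",
    "DepthRecord",
    "VariantObservation",
    "FailingInterval",
    "CoverageSummary",
    "VariantCall",
    "QcReport",
    "read_depth_table",
    "read_variant_observations",
    "assess_coverage",
    "classify_observation",
    "build_report",
    "write_report",
    "read_report_json",
    "write_failing_bed",
    "CALL_STATUSES",
]

logger = logging.getLogger(__name__)

CALL_STATUSES = (
    "positive",
    "negative",
    "below-LOD",
    "needs-confirmation",
    "insufficient-depth",
)

VARIANT_TSV_COLUMNS = ("chrom", "pos", "ref", "alt", "depth", "variant_reads")


class ParseError(ValueError):
    """Structured input-parsing failure carrying per-line messages."""

    def __init__(self, path, problems: Sequence[str]):
        self.path = str(path)
        self.problems = list(problems)
        msg = f"{self.path}: {len(self.problems)} malformed row(s)"
        if self.problems:
            msg += "; first: " + self.problems[0]
        super().__init__(msg)


@dataclass(frozen=True)
class DepthRecord:
    """Observed read depth at one genomic position (1-based)."""

    chrom: str
    pos: int
    depth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")


@dataclass(frozen=True)
class VariantObservation:
    """One candidate variant with its read support."""

    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    variant_reads: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.total_depth < 0 or self.variant_reads < 0:
            raise ValueError("depths must be non-negative")
        if self.variant_reads > self.total_depth:
            raise ValueError(
                f"variant_reads {self.variant_reads} exceeds total depth "
                f"{self.total_depth} at {self.chrom}:{self.pos}"
            )

    @property
    def vaf(self) -> float:
        return self.variant_reads / self.total_depth if self.total_depth else 0.0


# ---------------------------------------------------------------------------
# input


def read_depth_table(
    path, format: Literal["samtools-depth", "bed"] = "samtools-depth"
) -> list[DepthRecord]:
    """Read a per-base depth table.

    ``samtools-depth``: TSV of chrom, 1-based position, depth — one row
    per covered base.  ``bed``: 0-based half-open intervals with the
    depth in the fourth column, expanded per-base into 1-based records.
    """
    path = Path(path)
    if format not in ("samtools-depth", "bed"):
        raise ValueError(f"unknown depth-table format {format!r}")
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty depth table", path)
        return []

    problems: list[str] = []
    records: list[DepthRecord] = []
    ncols_needed = 3 if format == "samtools-depth" else 4
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        fields = [f for f in row]
        if len(fields) < ncols_needed or any(
            pd.isna(f) for f in fields[:ncols_needed]
        ):
            problems.append(f"line {line_no}: expected >= {ncols_needed} columns")
            continue
        try:
            if format == "samtools-depth":
                chrom, pos, depth = fields[0], int(fields[1]), int(fields[2])
                records.append(DepthRecord(chrom, pos, depth))
            else:
                chrom = fields[0]
                start, end, depth = int(fields[1]), int(fields[2]), int(fields[3])
                if start < 0 or end < start:
                    raise ValueError(f"bad interval [{start}, {end})")
                for pos in range(start + 1, end + 1):  # 0-based half-open -> 1-based
                    records.append(DepthRecord(chrom, pos, depth))
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise ParseError(path, problems)
    if not records:
        logger.warning("%s: depth table contains no positions", path)
    return records


def _vcf_observations(path) -> list[VariantObservation]:
    obs: list[VariantObservation] = []
    problems: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            if not list(rec.samples):
                problems.append(f"{rec.chrom}:{rec.pos}: no sample columns")
                continue
            sample = rec.samples[0]
            ad = sample.get("AD")
            dp = sample.get("DP")
            if ad is not None and not all(a is None for a in ad):
                ad = [int(a or 0) for a in ad]
                total = sum(ad)
                alt_counts = ad[1:]
            elif dp is not None:
                logger.warning(
                    "%s:%s: AD absent, falling back to DP without per-allele "
                    "counts", rec.chrom, rec.pos,
                )
                problems.append(
                    f"{rec.chrom}:{rec.pos}: AD absent; variant read count "
                    "not derivable from DP alone"
                )
                continue
            else:
                problems.append(f"{rec.chrom}:{rec.pos}: neither AD nor DP present")
                continue
            for alt, count in zip(rec.alts, alt_counts):
                try:
                    obs.append(
                        VariantObservation(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            total_depth=total,
                            variant_reads=count,
                        )
                    )
                except ValueError as exc:
                    problems.append(str(exc))
    if problems:
        raise ParseError(path, problems)
    return obs


def _tsv_observations(path) -> list[VariantObservation]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, [f"missing column(s): {', '.join(missing)}"])
    obs: list[VariantObservation] = []
    problems: list[str] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            obs.append(
                VariantObservation(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    total_depth=int(row.depth),
                    variant_reads=int(row.variant_reads),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise ParseError(path, problems)
    return obs


def read_variant_observations(
    path, format: Literal["vcf", "tsv"] = "vcf"
) -> list[VariantObservation]:
    """Read candidate variants.

    VCF: one observation per ALT allele of the first sample;
    ``variant_reads`` is that ALT's AD entry and ``total_depth`` the sum
    of all AD entries.  TSV: tab-separated with header columns
    ``chrom  pos  ref  alt  depth  variant_reads``.
    """
    if format == "vcf":
        return _vcf_observations(path)
    if format == "tsv":
        return _tsv_observations(path)
    raise ValueError(f"unknown variant format {format!r}")


# ---------------------------------------------------------------------------
# coverage assessment


@dataclass(frozen=True)
class FailingInterval:
    """Maximal run of positions below the required depth (1-based,
    inclusive internally; exported to BED as 0-based half-open)."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    min_depth: int


@dataclass(frozen=True)
class CoverageSummary:
    required_depth: int
    n_positions: int
    n_at_depth: int
    fraction_at_depth: float
    failing_intervals: tuple[FailingInterval, ...]


def assess_coverage(
    records: Sequence[DepthRecord], required_depth: int
) -> CoverageSummary:
    """Fraction of positions at or above the required depth, plus the
    merged, sorted maximal intervals that fall below it.

    Adjacent failing positions (consecutive coordinates on the same
    chromosome) merge into one interval.
    """
    if not records:
        raise ValueError("cannot assess coverage of an empty record list")
    if required_depth < 1:
        raise ValueError(f"required_depth must be >= 1, got {required_depth}")
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos))
    n_at = sum(1 for r in ordered if r.depth >= required_depth)
    intervals: list[FailingInterval] = []
    cur: list = []  # [chrom, start, end, min_depth]
    for r in ordered:
        if r.depth >= required_depth:
            continue
        if cur and r.chrom == cur[0] and r.pos == cur[2] + 1:
            cur[2] = r.pos
            cur[3] = min(cur[3], r.depth)
        else:
            if cur:
                intervals.append(FailingInterval(*cur))
            cur = [r.chrom, r.pos, r.pos, r.depth]
    if cur:
        intervals.append(FailingInterval(*cur))
    return CoverageSummary(
        required_depth=required_depth,
        n_positions=len(ordered),
        n_at_depth=n_at,
        fraction_at_depth=n_at / len(ordered),
        failing_intervals=tuple(intervals),
    )


# ---------------------------------------------------------------------------
# variant classification


@dataclass(frozen=True)
class VariantCall:
    """Classification of one observation against the design."""

    observation: VariantObservation
    status: str
    observed_vaf: float
    threshold_used: int | None

    def __post_init__(self) -> None:
        if self.status not in CALL_STATUSES:
            raise ValueError(f"unknown call status {self.status!r}")


def classify_observation(
    obs: VariantObservation,
    decision: ThresholdDecision,
    design: DetectionDesign,
    lod: float | None = None,
    confirmation_band: tuple[float, float] = (0.01, 0.03),
) -> VariantCall:
    """Classify a variant observation under a solved design.

    Depth below the design depth gates the call as insufficient-depth.
    Otherwise the threshold is re-solved at the observed depth and the
    inclusive rule applied; positives whose observed VAF falls below the
    LOD are labelled below-LOD, and positives inside the confirmation
    band (default 1-3% VAF, the range where replication or an
    orthogonal method is advisable) needs-confirmation.
    """
    low, high = confirmation_band
    if low > high:
        raise ValueError(f"confirmation band low {low} > high {high}")
    if lod is None:
        lod = design.vaf
    vaf = obs.vaf
    if obs.total_depth < decision.depth:
        return VariantCall(obs, "insufficient-depth", vaf, None)
    k = min_variant_reads(obs.total_depth, design.error, design.alpha_fp)
    if obs.variant_reads < k:
        return VariantCall(obs, "negative", vaf, k)
    if vaf < lod:
        return VariantCall(obs, "below-LOD", vaf, k)
    if low <= vaf <= high:
        return VariantCall(obs, "needs-confirmation", vaf, k)
    return VariantCall(obs, "positive", vaf, k)


# ---------------------------------------------------------------------------
# report


@dataclass(frozen=True)
class QcReport:
    """The recommended disclosure set for a diagnostic NGS assay:
    design parameters, coverage attainment, and per-variant read
    support, plus free-text DNA provenance metadata carried through
    unmodified."""

    lod: float
    overall_error: float
    alpha_fp: float
    min_detection: float
    required_depth: int
    threshold: int
    coverage: CoverageSummary | None
    variants: tuple[VariantCall, ...]
    dna_input: str = ""
    dna_source: str = ""
    dna_quality: str = ""
    software_version: str = ""
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "design": {
                "lod": self.lod,
                "overall_error": self.overall_error,
                "alpha_fp": self.alpha_fp,
                "min_detection": self.min_detection,
                "required_depth": self.required_depth,
                "threshold": self.threshold,
            },
            "metadata": {
                "dna_input": self.dna_input,
                "dna_source": self.dna_source,
                "dna_quality": self.dna_quality,
                "software_version": self.software_version,
                "seed": self.seed,
            },
            "coverage": None
            if self.coverage is None
            else {
                "required_depth": self.coverage.required_depth,
                "n_positions": self.coverage.n_positions,
                "n_at_depth": self.coverage.n_at_depth,
                "fraction_at_depth": self.coverage.fraction_at_depth,
                "failing_intervals": [
                    {
                        "chrom": iv.chrom,
                        "start": iv.start,
                        "end": iv.end,
                        "min_depth": iv.min_depth,
                    }
                    for iv in self.coverage.failing_intervals
                ],
            },
            "variants": [
                {
                    "chrom": c.observation.chrom,
                    "pos": c.observation.pos,
                    "ref": c.observation.ref,
                    "alt": c.observation.alt,
                    "total_depth": c.observation.total_depth,
                    "variant_reads": c.observation.variant_reads,
                    "observed_vaf": c.observed_vaf,
                    "threshold_used": c.threshold_used,
                    "status": c.status,
                }
                for c in self.variants
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QcReport":
        cov = d.get("coverage")
        coverage = None
        if cov is not None:
            coverage = CoverageSummary(
                required_depth=cov["required_depth"],
                n_positions=cov["n_positions"],
                n_at_depth=cov["n_at_depth"],
                fraction_at_depth=cov["fraction_at_depth"],
                failing_intervals=tuple(
                    FailingInterval(
                        iv["chrom"], iv["start"], iv["end"], iv["min_depth"]
                    )
                    for iv in cov["failing_intervals"]
                ),
            )
        variants = tuple(
            VariantCall(
                observation=VariantObservation(
                    chrom=v["chrom"],
                    pos=v["pos"],
                    ref=v["ref"],
                    alt=v["alt"],
                    total_depth=v["total_depth"],
                    variant_reads=v["variant_reads"],
                ),
                status=v["status"],
                observed_vaf=v["observed_vaf"],
                threshold_used=v["threshold_used"],
            )
            for v in d["variants"]
        )
        des, meta = d["design"], d["metadata"]
        return cls(
            lod=des["lod"],
            overall_error=des["overall_error"],
            alpha_fp=des["alpha_fp"],
            min_detection=des["min_detection"],
            required_depth=des["required_depth"],
            threshold=des["threshold"],
            coverage=coverage,
            variants=variants,
            dna_input=meta["dna_input"],
            dna_source=meta["dna_source"],
            dna_quality=meta["dna_quality"],
            software_version=meta["software_version"],
            seed=meta["seed"],
        )


def build_report(
    design: DetectionDesign,
    decision: ThresholdDecision,
    depth_records: Sequence[DepthRecord] = (),
    observations: Sequence[VariantObservation] = (),
    confirmation_band: tuple[float, float] = (0.01, 0.03),
    dna_input: str = "",
    dna_source: str = "",
    dna_quality: str = "",
    software_version: str = "",
    seed: int | None = None,
) -> QcReport:
    """Assemble a full QC report from raw inputs and a solved design."""
    coverage = (
        assess_coverage(depth_records, decision.depth) if depth_records else None
    )
    calls = tuple(
        classify_observation(
            o, decision, design, confirmation_band=confirmation_band
        )
        for o in observations
    )
    return QcReport(
        lod=design.vaf,
        overall_error=design.error,
        alpha_fp=design.alpha_fp,
        min_detection=design.min_detection,
        required_depth=decision.depth,
        threshold=decision.min_variant_reads,
        coverage=coverage,
        variants=calls,
        dna_input=dna_input,
        dna_source=dna_source,
        dna_quality=dna_quality,
        software_version=software_version,
        seed=seed,
    )


def _report_tsv(report: QcReport) -> str:
    d = report.to_dict()
    lines = []
    for key, val in {**d["design"], **d["metadata"]}.items():
        lines.append(f"# {key}={val}")
    if d["coverage"] is not None:
        cov = d["coverage"]
        lines.append(
            f"# fraction_at_depth={cov['fraction_at_depth']!r} "
            f"({cov['n_at_depth']}/{cov['n_positions']} positions >= "
            f"{cov['required_depth']}x)"
        )
        for iv in cov["failing_intervals"]:
            lines.append(
                f"# failing_interval={iv['chrom']}:{iv['start']}-{iv['end']} "
                f"min_depth={iv['min_depth']}"
            )
    cols = (
        "chrom", "pos", "ref", "alt", "total_depth", "variant_reads",
        "observed_vaf", "threshold_used", "status",
    )
    lines.append("\t".join(cols))
    for v in d["variants"]:
        lines.append(
            "\t".join(
                "NA" if v[c] is None else (repr(v[c]) if isinstance(v[c], float) else str(v[c]))
                for c in cols
            )
        )
    return "\n".join(lines) + "\n"


def write_report(report: QcReport, path, format: Literal["tsv", "json"] = "tsv") -> None:
    """Write the report; JSON is a stable schema that round-trips
    through :func:`read_report_json`."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    elif format == "tsv":
        path.write_text(_report_tsv(report))
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path) -> QcReport:
    return QcReport.from_dict(json.loads(Path(path).read_text()))


def write_failing_bed(summary: CoverageSummary, path) -> None:
    """Failing intervals as BED (0-based, half-open), score = min depth."""
    lines = [
        f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tbelow_{summary.required_depth}x\t{iv.min_depth}"
        for iv in summary.failing_intervals
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
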