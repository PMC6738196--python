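"""Coverage-depth and variant-read-threshold design.

The design problem: an assay wants to call variants down to a limit of
detection (LOD) ``f`` (a VAF), on a platform whose effective per-base
error rate is ``e``, while keeping the per-position false-positive
probability at or below ``alpha_fp`` and the probability of detecting a
true variant at the LOD at or above ``min_detection``.

With X ~ Binomial(depth, p) and the inclusive calling rule
"call variant iff variant-supporting reads X >= k":

* the threshold for a given depth is the smallest k whose chance of
  being reached by error alone is tolerable,
  ``k* = min {k : P(X >= k | depth, e) <= alpha_fp}``;
* the minimum depth for the LOD is the smallest depth at which that
  threshold still detects a true variant reliably,
  ``P(X >= k* | depth, f) >= min_detection``.

Because k* jumps discretely as depth grows, satisfaction is not
monotone in depth (a sawtooth): a depth can satisfy the design while
some larger depths do not.  ``min_depth`` therefore exposes two
policies: ``first`` (smallest satisfying depth, the default) and
``stable`` (smallest depth from which the design holds over a whole
window of subsequent depths).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .binom import TrialParams, tail_geq

__all__ = [
    "DesignError",
    "InfeasibleDesignError",
    "DepthNotFoundError",
    "AssayErrorModel",
    "DetectionDesign",
    "ThresholdDecision",
    "LodCurvePoint",
    "overall_error",
    "min_variant_reads",
    "detection_probability",
    "false_negative_probability",
    "evaluate_design",
    "min_depth",
    "lod_curve",
    "curve_to_tsv",
    "curve_to_json",
    "format_percent",
]

DEFAULT_SEARCH_MAX = 100_000
DEFAULT_STABLE_WINDOW = 50

CURVE_COLUMNS = (
    "vaf",
    "alpha_fp",
    "min_detection",
    "error",
    "min_depth",
    "threshold",
    "fp_prob",
    "detection_prob",
)


class DesignError(ValueError):
    """Base class for design-problem errors."""


class InfeasibleDesignError(DesignError):
    """The error rate is at or above the intended LOD: no threshold can
    separate signal from noise at any depth."""


class DepthNotFoundError(DesignError):
    """No depth within the search range satisfies the design."""


def format_percent(x: float, decimals: int = 2) -> str:
    """Render a probability as a percentage for human-readable output.

    Rounding happens only here; all machine output carries full
    precision.
    """
    return f"{100.0 * x:.{decimals}f}%"


# ---------------------------------------------------------------------------
# error composition


@dataclass(frozen=True)
class AssayErrorModel:
    """Per-base error budget of an NGS assay.

    ``sequencing_error`` is the intrinsic platform error (Phred Q20-Q30
    is roughly 1-0.1%).  ``assay_errors`` are additional per-base error
    components introduced during DNA processing and library preparation
    (PCR errors and the like).  Components compose additively; the sum
    is what the design solver uses as its effective error rate.
    """

    sequencing_error: float
    assay_errors: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        components = (self.sequencing_error, *self.assay_errors)
        for c in components:
            if not 0.0 <= c < 1.0:
                raise ValueError(f"error component {c} outside [0, 1)")
        if sum(components) >= 1.0:
            raise ValueError(
                f"overall error {sum(components)} must be below 1"
            )
        object.__setattr__(self, "assay_errors", tuple(self.assay_errors))

    @property
    def overall_error(self) -> float:
        # normalised to 12 significant digits so that composing decimal
        # components reproduces the directly-typed decimal sum
        total = self.sequencing_error + sum(self.assay_errors)
        return float(f"{total:.12g}")


def overall_error(model: AssayErrorModel) -> float:
    """Additive composition of sequencing and assay-specific errors."""
    return model.overall_error


# ---------------------------------------------------------------------------
# design definition


@dataclass(frozen=True)
class DetectionDesign:
    """One coverage-design problem.

    Parameters
    ----------
    vaf
        Intended LOD as a variant allele fraction, in (0, 1].
    error
        Effective per-base error rate (use
        :class:`AssayErrorModel` / :func:`overall_error` to fold in
        assay-specific components), in [0, 1) and strictly below
        ``vaf``.
    alpha_fp
        Maximum tolerated per-position false-positive probability.
    min_detection
        Required probability of detecting a true variant at the LOD.
    """

    vaf: float
    error: float
    alpha_fp: float
    min_detection: float

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError(f"vaf must be in (0, 1], got {self.vaf}")
        if not 0.0 <= self.error < 1.0:
            raise ValueError(f"error must be in [0, 1), got {self.error}")
        if not 0.0 < self.alpha_fp < 1.0:
            raise ValueError(f"alpha_fp must be in (0, 1), got {self.alpha_fp}")
        if not 0.0 < self.min_detection < 1.0:
            raise ValueError(
                f"min_detection must be in (0, 1), got {self.min_detection}"
            )
        if self.error >= self.vaf:
            raise InfeasibleDesignError(
                f"error rate {self.error} >= LOD {self.vaf}: error reads are "
                "at least as frequent as variant reads, no threshold can "
                "separate them"
            )
        if self.vaf < 2.0 * self.error:
            warnings.warn(
                f"LOD {self.vaf} is below twice the error rate {self.error}; "
                "calls this close to the noise floor carry a high "
                "false-positive risk",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class ThresholdDecision:
    """A solved (depth, threshold) pair with its operating probabilities.

    ``fp_prob`` is P(X >= k | depth, error): the chance error reads alone
    reach the threshold at a wild-type position.  ``detection_prob`` is
    P(X >= k | depth, vaf) and ``fn_prob`` its complement: the chance a
    true variant at the LOD is missed.
    """

    depth: int
    min_variant_reads: int
    fp_prob: float
    detection_prob: float
    fn_prob: float
    fp_satisfied: bool
    tp_satisfied: bool

    @property
    def satisfied(self) -> bool:
        return self.fp_satisfied and self.tp_satisfied


@dataclass(frozen=True)
class LodCurvePoint:
    """One point of a LOD-versus-depth curve.

    ``status`` is ``"ok"`` for a solved point, ``"infeasible"`` when the
    LOD does not exceed the error rate, and ``"not-found"`` when no
    depth within the search range satisfies the design.
    """

    vaf: float
    setting: tuple[float, float]  # (alpha_fp, min_detection)
    error: float
    min_depth: int | None
    threshold: int | None
    fp_prob: float | None = None
    detection_prob: float | None = None
    status: str = "ok"


# ---------------------------------------------------------------------------
# solvers


def min_variant_reads(depth: int, error: float, alpha_fp: float) -> int:
    """Smallest threshold k with P(X >= k | depth, error) <= alpha_fp.

    A count of k or more variant reads then has probability at most
    ``alpha_fp`` of arising from sequencing error alone.  The tail
    P(X >= k) is non-increasing in k, so the minimal k is found by
    bisection over [0, depth + 1].
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if not 0.0 <= error < 1.0:
        raise ValueError(f"error must be in [0, 1), got {error}")
    if not 0.0 < alpha_fp < 1.0:
        raise ValueError(f"alpha_fp must be in (0, 1), got {alpha_fp}")
    params = TrialParams(depth, error)
    lo, hi = 0, depth + 1
    while lo < hi:
        mid = (lo + hi) // 2
        if tail_geq(mid, params) <= alpha_fp:
            hi = mid
        else:
            lo = mid + 1
    return lo


def detection_probability(depth: int, threshold: int, vaf: float) -> float:
    """P(X >= threshold | depth, vaf): chance the calling rule fires on a
    true variant present at the given allele fraction."""
    return tail_geq(threshold, TrialParams(depth, vaf))


def false_negative_probability(depth: int, threshold: int, vaf: float) -> float:
    """P(X <= threshold - 1 | depth, vaf): chance a true variant at the
    given VAF yields too few variant reads and is missed."""
    from .binom import cdf

    params = TrialParams(depth, vaf)
    if threshold == 0:
        return 0.0
    return cdf(threshold - 1, params)


def evaluate_design(
    depth: int, threshold: int, design: DetectionDesign
) -> ThresholdDecision:
    """Operating characteristics of an arbitrary (depth, threshold) pair
    under a design, with satisfaction flags for both constraints."""
    if not 0 <= threshold <= depth:
        raise ValueError(
            f"threshold {threshold} outside [0, depth={depth}]"
        )
    fp = tail_geq(threshold, TrialParams(depth, design.error))
    det = detection_probability(depth, threshold, design.vaf)
    fn = false_negative_probability(depth, threshold, design.vaf)
    return ThresholdDecision(
        depth=depth,
        min_variant_reads=threshold,
        fp_prob=fp,
        detection_prob=det,
        fn_prob=fn,
        fp_satisfied=fp <= design.alpha_fp,
        tp_satisfied=det >= design.min_detection,
    )


def _solve_at_depth(depth: int, design: DetectionDesign) -> ThresholdDecision:
    k = min_variant_reads(depth, design.error, design.alpha_fp)
    if k > depth:
        # even k = depth is reachable by error alone too often
        return ThresholdDecision(
            depth=depth,
            min_variant_reads=k,
            fp_prob=tail_geq(min(k, depth + 1), TrialParams(depth, design.error)),
            detection_prob=0.0,
            fn_prob=1.0,
            fp_satisfied=True,
            tp_satisfied=False,
        )
    return evaluate_design(depth, k, design)


def min_depth(
    design: DetectionDesign,
    search_max: int = DEFAULT_SEARCH_MAX,
    policy: Literal["first", "stable"] = "first",
    window: int = DEFAULT_STABLE_WINDOW,
) -> ThresholdDecision:
    """Smallest coverage depth whose error-calibrated threshold meets the
    detection requirement.

    Ascending linear scan from depth 1.  Under ``policy="first"`` the
    first satisfying depth is returned; because the threshold k jumps
    discretely with depth, some larger depths may violate the design
    again (sawtooth).  Under ``policy="stable"`` the smallest depth n
    such that every depth in [n, n + window] satisfies the design is
    returned, trading a somewhat larger answer for sawtooth immunity.
    """
    if search_max < 1:
        raise ValueError(f"search_max must be >= 1, got {search_max}")
    if policy not in ("first", "stable"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "first":
        for depth in range(1, search_max + 1):
            decision = _solve_at_depth(depth, design)
            if decision.satisfied:
                return decision
        raise DepthNotFoundError(
            f"no depth <= {search_max} satisfies the design {design}"
        )
    # stable: first depth opening a run of window+1 consecutive satisfying depths
    run_start: int | None = None
    run_len = 0
    for depth in range(1, search_max + window + 1):
        if _solve_at_depth(depth, design).satisfied:
            if run_start is None:
                run_start = depth
            run_len += 1
            if run_len == window + 1 and run_start <= search_max:
                return _solve_at_depth(run_start, design)
        else:
            run_start, run_len = None, 0
    raise DepthNotFoundError(
        f"no depth <= {search_max} opens a stable satisfying window of "
        f"{window} under the design {design}"
    )


def lod_curve(
    vafs: Sequence[float],
    error: float,
    settings: Sequence[tuple[float, float]],
    search_max: int = DEFAULT_SEARCH_MAX,
    policy: Literal["first", "stable"] = "first",
) -> list[LodCurvePoint]:
    """Minimum depth and threshold per (LOD, setting) combination.

    Output is ordered by setting, then by descending VAF.  Infeasible or
    unsolvable points are marked in ``status`` rather than aborting the
    curve.
    """
    points: list[LodCurvePoint] = []
    for alpha_fp, min_detection in settings:
        for vaf in sorted(vafs, reverse=True):
            try:
                design = DetectionDesign(
                    vaf=vaf,
                    error=error,
                    alpha_fp=alpha_fp,
                    min_detection=min_detection,
                )
            except InfeasibleDesignError:
                points.append(
                    LodCurvePoint(
                        vaf=vaf,
                        setting=(alpha_fp, min_detection),
                        error=error,
                        min_depth=None,
                        threshold=None,
                        status="infeasible",
                    )
                )
                continue
            try:
                d = min_depth(design, search_max=search_max, policy=policy)
            except DepthNotFoundError:
                points.append(
                    LodCurvePoint(
                        vaf=vaf,
                        setting=(alpha_fp, min_detection),
                        error=error,
                        min_depth=None,
                        threshold=None,
                        status="not-found",
                    )
                )
                continue
            points.append(
                LodCurvePoint(
                    vaf=vaf,
                    setting=(alpha_fp, min_detection),
                    error=error,
                    min_depth=d.depth,
                    threshold=d.min_variant_reads,
                    fp_prob=d.fp_prob,
                    detection_prob=d.detection_prob,
                )
            )
    return points


# ---------------------------------------------------------------------------
# export


def _point_row(p: LodCurvePoint) -> dict:
    return {
        "vaf": p.vaf,
        "alpha_fp": p.setting[0],
        "min_detection": p.setting[1],
        "error": p.error,
        "min_depth": p.min_depth,
        "threshold": p.threshold,
        "fp_prob": p.fp_prob,
        "detection_prob": p.detection_prob,
        "status": p.status,
    }


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return repr(v)  # >= 12 significant digits round-trip
    return str(v)


def curve_to_tsv(points: Iterable[LodCurvePoint], header_lines: Sequence[str] = ()) -> str:
    """Render curve points as TSV; ``header_lines`` become '#'-prefixed
    metadata lines (parameters, version, seed)."""
    cols = (*CURVE_COLUMNS, "status")
    out = [f"# {line}" for line in header_lines]
    out.append("\t".join(cols))
    for p in points:
        row = _point_row(p)
        out.append("\t".join(_fmt(row[c]) for c in cols))
    return "\n".join(out) + "\n"


def curve_to_json(points: Iterable[LodCurvePoint], metadata: dict | None = None) -> str:
    payload = {
        "metadata": metadata or {},
        "points": [_point_row(p) for p in points],
    }
    return json.dumps(payload, indent=2) + "\n"
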