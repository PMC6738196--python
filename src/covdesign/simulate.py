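"""Monte-Carlo validation of the binomial coverage design.

Draws read-count outcomes under the same generative model the analytics
assume — variant-supporting reads of a mutant sample are
Binomial(depth, VAF), spurious variant reads at a wild-type position are
Binomial(depth, error) — applies the calling rule X >= threshold, and
compares empirical false-negative / false-positive rates with the exact
binomial probabilities.  Error reads are not added on top of the VAF for
mutant samples; the two regimes are simulated separately, mirroring the
analytic model.

Also emulates, in silico, a dilution series: a ladder of VAF levels
sequenced at fixed depth with a fixed calling threshold, reporting the
detection shortfall per level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .binom import TrialParams, tail_geq
from .design import false_negative_probability

__all__ = [
    "SimulationSpec",
    "SimulationResult",
    "draw_variant_read_counts",
    "estimate_rates",
    "dilution_experiment",
    "results_to_tsv",
]

RESULT_COLUMNS = (
    "truth",
    "vaf",
    "depth",
    "threshold",
    "replicates",
    "called_positive",
    "empirical_rate",
    "analytic_rate",
    "mc_stderr",
    "seed",
)


@dataclass(frozen=True)
class SimulationSpec:
    """One simulation scenario.

    ``truth`` selects the regime: ``"mutant"`` simulates a true variant
    present at allele fraction ``p`` and reports the false-negative
    rate; ``"wildtype"`` simulates a variant-free position with per-base
    error rate ``p`` and reports the false-positive rate.
    """

    depth: int
    threshold: int
    p: float
    truth: Literal["mutant", "wildtype"] = "mutant"
    replicates: int = 100_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if not 0 <= self.threshold <= self.depth:
            raise ValueError(
                f"threshold {self.threshold} outside [0, depth={self.depth}]"
            )
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.truth not in ("mutant", "wildtype"):
            raise ValueError(f"unknown truth {self.truth!r}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")


@dataclass(frozen=True)
class SimulationResult:
    """Empirical versus analytic error rate for one scenario.

    ``empirical_rate`` is the FN rate for mutant truth and the FP rate
    for wild-type truth; ``analytic_rate`` is the matching exact
    binomial probability and ``mc_stderr`` the binomial standard error
    sqrt(p(1-p)/replicates) of the empirical estimate at that rate.
    """

    spec: SimulationSpec
    called_positive: int
    replicates: int
    empirical_rate: float
    analytic_rate: float
    mc_stderr: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.called_positive <= self.replicates:
            raise ValueError("called_positive outside [0, replicates]")


def draw_variant_read_counts(
    depth: int,
    p: float,
    replicates: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """``replicates`` independent draws of X ~ Binomial(depth, p).

    Identical integer seed gives an identical sequence (PCG64 via
    :func:`numpy.random.default_rng`).
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(depth, p, size=replicates)


def estimate_rates(spec: SimulationSpec) -> SimulationResult:
    """Simulate the calling rule and report empirical vs analytic rates.

    When the spec carries no seed, one is drawn from OS entropy and
    recorded in the result so the run can be reproduced.
    """
    seed = spec.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    counts = draw_variant_read_counts(spec.depth, spec.p, spec.replicates, seed)
    called = int(np.count_nonzero(counts >= spec.threshold))
    if spec.truth == "mutant":
        empirical = (spec.replicates - called) / spec.replicates  # FN rate
        analytic = false_negative_probability(spec.depth, spec.threshold, spec.p)
    else:
        empirical = called / spec.replicates  # FP rate
        analytic = tail_geq(spec.threshold, TrialParams(spec.depth, spec.p))
    stderr = float(np.sqrt(analytic * (1.0 - analytic) / spec.replicates))
    return SimulationResult(
        spec=spec,
        called_positive=called,
        replicates=spec.replicates,
        empirical_rate=empirical,
        analytic_rate=analytic,
        mc_stderr=stderr,
        seed=seed,
    )


def dilution_experiment(
    vafs: Sequence[float],
    depth: int,
    threshold: int,
    replicates_per_level: int,
    seed: int | None = None,
) -> list[SimulationResult]:
    """In-silico dilution series: one mutant-truth scenario per VAF level.

    Levels are processed in descending VAF order (the order a wet-lab
    dilution ladder is reported in), each with an independent child
    stream spawned from ``seed`` so that adding or removing a level does
    not perturb the others.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(vafs))
    results: list[SimulationResult] = []
    order = sorted(range(len(vafs)), key=lambda i: -vafs[i])
    for rank, i in enumerate(order):
        child_seed = int(children[i].generate_state(1, dtype=np.uint32)[0] % (2**31))
        spec = SimulationSpec(
            depth=depth,
            threshold=threshold,
            p=vafs[i],
            truth="mutant",
            replicates=replicates_per_level,
            seed=child_seed,
        )
        results.append(estimate_rates(spec))
    return results


def results_to_tsv(
    results: Iterable[SimulationResult], header_lines: Sequence[str] = ()
) -> str:
    """Render results as TSV with '#'-prefixed metadata header lines."""
    out = [f"# {line}" for line in header_lines]
    out.append("\t".join(RESULT_COLUMNS))
    for r in results:
        out.append(
            "\t".join(
                str(v)
                for v in (
                    r.spec.truth,
                    repr(r.spec.p),
                    r.spec.depth,
                    r.spec.threshold,
                    r.replicates,
                    r.called_positive,
                    repr(r.empirical_rate),
                    repr(r.analytic_rate),
                    repr(r.mc_stderr),
                    r.seed,
                )
            )
        )
    return "\n".join(out) + "\n"
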