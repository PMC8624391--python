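"""Domain types shared across the pipeline.

The analysis operates on an introgression-line (IL) library: near-isogenic
lines each carrying one (or more) marker-defined chromosomal segments from a
wild donor in an elite recurrent-parent background, positioned on a
centimorgan genetic map.  Phenotypes are replicated trait observations per
line x treatment, optionally backed by daily germination counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

DEFAULT_CHROMOSOMES = ("1H", "2H", "3H", "4H", "5H", "6H", "7H")
DEFAULT_TREATMENTS = ("control", "75mM", "150mM")


class ValidationError(ValueError):
    """Raised when an input violates a declared type invariant."""


@dataclass(frozen=True, order=True)
class GeneticInterval:
    """A closed interval [start, end] on a genetic map, in centimorgans.

    Overlap is defined on closed intervals, so a shared endpoint counts as
    overlapping.
    """

    chromosome: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(
                f"interval start must be >= 0 cM, got {self.start}"
            )
        if self.start > self.end:
            raise ValidationError(
                f"inverted interval on {self.chromosome}: "
                f"start {self.start} > end {self.end}"
            )

    def overlaps(self, other: "GeneticInterval") -> bool:
        if self.chromosome != other.chromosome:
            return False
        return self.start <= other.end and other.start <= self.end

    def contains(self, position: float) -> bool:
        return self.start <= position <= self.end

    def union_span(self, other: "GeneticInterval") -> "GeneticInterval":
        if self.chromosome != other.chromosome:
            raise ValidationError("cannot span intervals on different chromosomes")
        return GeneticInterval(
            self.chromosome, min(self.start, other.start), max(self.end, other.end)
        )

    def __str__(self) -> str:
        return f"{self.chromosome} {self.start:g}-{self.end:g}"


@dataclass(frozen=True)
class IntrogressionLine:
    """One IL: a line identifier plus its donor-segment interval(s)."""

    line_id: str
    intervals: tuple[GeneticInterval, ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValidationError(f"line {self.line_id!r} has no intervals")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for iv in self.intervals:
            if iv.chromosome not in seen:
                seen.append(iv.chromosome)
        return tuple(seen)


@dataclass(frozen=True)
class GerminationCounts:
    """Daily counts of newly germinated seeds for one replicate box.

    ``daily_counts[d-1]`` is the number of seeds that germinated on day d of
    the observation window (default 10 days).  Seeds that never germinate
    within the window simply do not appear in the counts.
    """

    line_id: str
    treatment: str
    replicate: int
    sown: int
    daily_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.sown < 1:
            raise ValidationError("sown must be a positive integer")
        if any(c < 0 for c in self.daily_counts):
            raise ValidationError("daily counts must be non-negative")
        if sum(self.daily_counts) > self.sown:
            raise ValidationError(
                f"germinated total {sum(self.daily_counts)} exceeds sown {self.sown} "
                f"({self.line_id}/{self.treatment}/rep{self.replicate})"
            )

    @property
    def total_germinated(self) -> int:
        return sum(self.daily_counts)

    @property
    def window(self) -> int:
        return len(self.daily_counts)


@dataclass
class AnalysisConfig:
    """Thresholds and design constants for the QTL scan.

    ``alpha_interaction`` (default 0.01) is the Dunnett-adjusted p threshold
    used for the line x treatment interaction call; ``alpha_main`` (default
    0.05) for the line main-effect call.
    """

    control_line_id: str = "Scarlett"
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    replicates: int = 3
    alpha_interaction: float = 0.01
    alpha_main: float = 0.05
    rng_seed: int = 0
    dunnett_tolerance: float = 1e-3
    library_label: str = "LIB"
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES

    def __post_init__(self) -> None:
        if not (0 < self.alpha_interaction <= self.alpha_main < 1):
            raise ValidationError(
                "require 0 < alpha_interaction <= alpha_main < 1, got "
                f"{self.alpha_interaction}, {self.alpha_main}"
            )
        if self.replicates < 2:
            raise ValidationError("need at least 2 replicates")

    @property
    def control_treatment(self) -> str:
        return self.treatments[0]


def check_library(lines: Sequence[IntrogressionLine],
                  chromosomes: Sequence[str] | None = None) -> None:
    """Validate library-level invariants: unique line ids, known chromosomes."""
    seen: set[str] = set()
    for line in lines:
        if line.line_id in seen:
            raise ValidationError(f"duplicate line_id {line.line_id!r} in library")
        seen.add(line.line_id)
        if chromosomes is not None:
            for iv in line.intervals:
                if iv.chromosome not in chromosomes:
                    raise ValidationError(
                        f"unknown chromosome {iv.chromosome!r} for line {line.line_id!r}"
                    )
    if not lines:
        warnings.warn("empty IL library", stacklevel=2)
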