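"""Synthetic IL-library experiments with planted QTL.

The generator emulates the design the analysis assumes: ~50 introgression
lines plus the recurrent parent, each line carrying one donor segment on a
7-chromosome centimorgan map; three treatments (control, 75 mM, 150 mM
NaCl); three replicate boxes of 45 seeds; a 10-day germination window.

Germination is modelled per seed: a seed germinates with probability
p(line, treatment) (logistic in a baseline logit + treatment shift + any
planted germination effect) and, conditionally, its germination day is a
discretised gamma whose mean rises under salt (salinity both lowers final
germination and delays it).  Seeds whose latent day exceeds the window count
as non-germinated.

Measured seedling primitives follow the additive two-way model

    value(line, treatment, rep) = mu_trait + T(treatment) + Q(line, treatment) + eps,

eps ~ N(0, sigma_trait), where Q is the planted-QTL shift (expressed in
residual-SD units in the recipe).  Derived traits (SL, RSR, SVI, WCP) are
composed from the primitives, so their internal consistency holds by
construction.  Default treatment means and residual SDs are set to values
realistic for barley germination/seedling assays under these salt levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .types import GeneticInterval, GerminationCounts, IntrogressionLine

DEFAULT_CHROMOSOME_LENGTHS = {
    "1H": 150.0, "2H": 160.0, "3H": 170.0, "4H": 150.0,
    "5H": 180.0, "6H": 130.0, "7H": 160.0,
}

#: per-treatment means and residual SD of the simulated seedling primitives
DEFAULT_TRAIT_MODELS = {
    # trait: ((control, 75mM, 150mM means), residual sd)
    "ShL": ((9.5, 6.0, 4.1), 1.0),
    "RL": ((10.6, 8.0, 6.0), 0.9),
    "SFW": ((253.0, 182.0, 166.0), 28.0),
    "SDW": ((27.8, 23.0, 34.3), 5.0),
}

DEFAULT_GERMINATION_PROB = (0.93, 0.83, 0.82)   # final germination, by treatment
DEFAULT_GERMINATION_MGT = (3.1, 3.7, 3.3)       # mean germination day, by treatment


class ConfigError(ValueError):
    """An inconsistent simulation recipe."""


@dataclass(frozen=True)
class PlantedQtl:
    """Ground truth for one planted effect.

    ``effect_by_treatment`` holds the additive shift per treatment in trait
    units (for germination, on the logit scale).  ``sign`` is the shared sign
    of the non-zero shifts.
    """

    line_id: str
    interval: GeneticInterval
    trait: str
    effect_by_treatment: Mapping[str, float]
    sign: int

    def __post_init__(self) -> None:
        nonzero = [v for v in self.effect_by_treatment.values() if v != 0.0]
        if not nonzero:
            raise ConfigError("planted QTL needs at least one non-zero shift")
        signs = {1 if v > 0 else -1 for v in nonzero}
        if signs != {self.sign}:
            raise ConfigError("planted-QTL sign inconsistent with its shifts")


@dataclass
class SimulationRecipe:
    """All knobs of the generator, with study-design defaults."""

    n_lines: int = 50
    chromosome_lengths: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOME_LENGTHS))
    treatments: tuple[str, ...] = ("control", "75mM", "150mM")
    replicates: int = 3
    seeds_per_rep: int = 45
    window: int = 10
    interval_length_range: tuple[float, float] = (10.0, 60.0)
    n_planted_qtl: int = 8
    effect_size_sd: float = 2.5
    germination_prob: tuple[float, ...] = DEFAULT_GERMINATION_PROB
    germination_mgt: tuple[float, ...] = DEFAULT_GERMINATION_MGT
    germination_day_shape: float = 6.0
    germination_logit_effect: float = 1.0
    trait_models: Mapping[str, tuple[tuple[float, ...], float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_MODELS))
    control_line_id: str = "Scarlett"
    line_id_prefix: str = "IL"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_qtl > self.n_lines:
            raise ConfigError("n_planted_qtl cannot exceed n_lines")
        if self.seeds_per_rep < 1:
            raise ConfigError("seeds_per_rep must be >= 1")
        if any(l <= 0 for l in self.chromosome_lengths.values()):
            raise ConfigError("map lengths must be positive")
        if not all(0.0 < p < 1.0 for p in self.germination_prob):
            raise ConfigError("germination probabilities must lie in (0, 1)")
        if not math.isfinite(self.effect_size_sd):
            raise ConfigError("effect size must be finite")


@dataclass
class SimulatedExperiment:
    library: list[IntrogressionLine]
    truth: list[PlantedQtl]
    germination: list[GerminationCounts]
    phenotypes: pd.DataFrame  # long format, primitives + derived traits


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def simulate_library(recipe: SimulationRecipe,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[list[IntrogressionLine], list[PlantedQtl]]:
    """Draw the IL library and the planted-QTL truth.

    Each line receives a single interval: chromosome uniform over the map,
    length uniform over ``interval_length_range``, start uniform and the
    interval clipped to the chromosome.  ``n_planted_qtl`` distinct lines are
    then assigned effects, cycling over the modelled traits (plus
    germination), alternating salt-only "interaction" patterns with
    all-treatment "main" patterns, and with both effect signs represented.
    """
    rng = np.random.default_rng(recipe.rng_seed) if rng is None else rng
    chroms = list(recipe.chromosome_lengths)
    lo, hi = recipe.interval_length_range
    library: list[IntrogressionLine] = []
    for i in range(recipe.n_lines):
        chrom = chroms[rng.integers(len(chroms))]
        clen = recipe.chromosome_lengths[chrom]
        length = min(rng.uniform(lo, hi), clen)
        start = rng.uniform(0.0, clen - length)
        iv = GeneticInterval(chrom, round(start, 1), round(start + length, 1))
        library.append(IntrogressionLine(
            f"{recipe.line_id_prefix}-{101 + i}", (iv,)))

    effect_traits = list(recipe.trait_models) + ["GP"]
    planted_lines = rng.choice(recipe.n_lines, size=recipe.n_planted_qtl,
                               replace=False)
    truth: list[PlantedQtl] = []
    salt = [t for t in recipe.treatments[1:]]
    for j, idx in enumerate(planted_lines):
        line = library[int(idx)]
        trait = effect_traits[j % len(effect_traits)]
        sign = 1 if j % 2 == 0 else -1
        if trait == "GP":
            size = sign * recipe.germination_logit_effect
        else:
            size = sign * recipe.effect_size_sd * recipe.trait_models[trait][1]
        # alternate line-main patterns (all treatments) with salt-only G x T
        if (j // 2) % 2 == 0:
            shifts = {t: size for t in recipe.treatments}
        else:
            shifts = {t: (size if t in salt else 0.0) for t in recipe.treatments}
        truth.append(PlantedQtl(line.line_id, line.intervals[0], trait,
                                shifts, sign))
    return library, truth


def _qtl_shift(truth: Sequence[PlantedQtl], line_id: str, trait: str,
               treatment: str) -> float:
    return sum(q.effect_by_treatment.get(treatment, 0.0)
               for q in truth if q.line_id == line_id and q.trait == trait)


def _day_probabilities(mean_day: float, shape: float,
                       window: int) -> np.ndarray:
    """Discretised gamma: P(day = d) = F(d) - F(d-1), d = 1..window."""
    from scipy import stats
    scale = mean_day / shape
    edges = stats.gamma.cdf(np.arange(window + 1), a=shape, scale=scale)
    return np.diff(edges)


def simulate_germination(recipe: SimulationRecipe,
                         library: Sequence[IntrogressionLine],
                         truth: Sequence[PlantedQtl],
                         rng: np.random.Generator | None = None,
                         ) -> list[GerminationCounts]:
    """Per-seed germination: Bernoulli success x discretised-gamma day."""
    rng = np.random.default_rng(recipe.rng_seed + 1) if rng is None else rng
    line_ids = [recipe.control_line_id] + [ln.line_id for ln in library]
    counts: list[GerminationCounts] = []
    day_probs = {t: _day_probabilities(recipe.germination_mgt[i],
                                       recipe.germination_day_shape,
                                       recipe.window)
                 for i, t in enumerate(recipe.treatments)}
    for line_id in line_ids:
        for ti, trt in enumerate(recipe.treatments):
            shift = (_qtl_shift(truth, line_id, "GP", trt)
                     if line_id != recipe.control_line_id else 0.0)
            p = 1.0 / (1.0 + math.exp(-(_logit(recipe.germination_prob[ti])
                                        + shift)))
            probs = p * day_probs[trt]
            cell = np.concatenate([probs, [1.0 - probs.sum()]])
            for rep in range(1, recipe.replicates + 1):
                draw = rng.multinomial(recipe.seeds_per_rep, cell)
                counts.append(GerminationCounts(
                    line_id, trt, rep, recipe.seeds_per_rep,
                    tuple(int(x) for x in draw[:-1])))
    return counts


def simulate_seedling_traits(recipe: SimulationRecipe,
                             library: Sequence[IntrogressionLine],
                             truth: Sequence[PlantedQtl],
                             germination: Sequence[GerminationCounts] | None = None,
                             rng: np.random.Generator | None = None,
                             ) -> pd.DataFrame:
    """Long-format phenotype table: primitives plus composed derived traits.

    If germination counts are supplied, GP/GI/MGT are summarised from them so
    SVI = GP x SL is consistent with the germination data; otherwise the
    seedling primitives alone are returned.  Non-positive shoot-length draws
    are truncated at a 0.1 cm floor to keep RSR defined.
    """
    rng = np.random.default_rng(recipe.rng_seed + 2) if rng is None else rng
    line_ids = [recipe.control_line_id] + [ln.line_id for ln in library]
    rows = []
    for line_id in line_ids:
        for ti, trt in enumerate(recipe.treatments):
            for trait, (mu_by_trt, sd) in recipe.trait_models.items():
                shift = (_qtl_shift(truth, line_id, trait, trt)
                         if line_id != recipe.control_line_id else 0.0)
                mean = mu_by_trt[ti] + shift
                draws = mean + sd * rng.standard_normal(recipe.replicates)
                if trait == "ShL":
                    draws = np.maximum(draws, 0.1)
                for rep, value in enumerate(draws, start=1):
                    rows.append({"line_id": line_id, "treatment": trt,
                                 "replicate": rep, "trait": trait,
                                 "value": float(value)})
    table = pd.DataFrame(rows, columns=["line_id", "treatment", "replicate",
                                        "trait", "value"])
    if germination is not None:
        table = pd.concat(
            [metrics.germination_metrics_table(germination), table],
            ignore_index=True)
    return metrics.derived_traits(table)


def simulate_experiment(recipe: SimulationRecipe) -> SimulatedExperiment:
    """Run the full generator with seeds derived from ``recipe.rng_seed``."""
    seeds = np.random.SeedSequence(recipe.rng_seed).spawn(3)
    library, truth = simulate_library(recipe, np.random.default_rng(seeds[0]))
    germ = simulate_germination(recipe, library, truth,
                                np.random.default_rng(seeds[1]))
    phen = simulate_seedling_traits(recipe, library, truth, germ,
                                    np.random.default_rng(seeds[2]))
    return SimulatedExperiment(library, truth, germ, phen)


def truth_table(truth: Sequence[PlantedQtl],
                treatments: Sequence[str]) -> pd.DataFrame:
    """Tabular form of the planted truth, suitable for write_results."""
    rows = []
    for q in truth:
        row = {"line_id": q.line_id, "trait": q.trait,
               "chromosome": q.interval.chromosome,
               "start_cM": q.interval.start, "end_cM": q.interval.end,
               "sign": q.sign}
        row.update({f"effect_{t}": q.effect_by_treatment.get(t, 0.0)
                    for t in treatments})
        rows.append(row)
    cols = (["line_id", "trait", "chromosome", "start_cM", "end_cM", "sign"]
            + [f"effect_{t}" for t in treatments])
    return pd.DataFrame(rows, columns=cols)
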