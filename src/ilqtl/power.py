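"""Simulation studies of the scan's operating characteristics.

Two study designs, both on the default library geometry (50 lines, three
treatments, three replicates) with a single measured trait so that repeated
simulation stays cheap:

* recovery: one planted QTL of a given size (residual-SD units, present in
  every treatment) -- how often does the fitted scan emit a call whose
  merged interval overlaps the truth, and how many calls land elsewhere?
* null calibration: no planted effects -- how many line x trait associations
  (and interaction-class associations) appear per simulated library?

Under the null the marginal distribution of each Dunnett t statistic is an
ordinary Student t, so the per-line probability that its adjusted p falls
below alpha is available analytically from the max-|T| critical value;
treatment contexts are independent, making the expected count of
interaction-class lines (significant in exactly one or two of the three
treatments) a closed-form binomial expression.  The simulation studies are
compared against that expectation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scan import QtlScan
from .simulate import SimulationRecipe, simulate_library, simulate_seedling_traits
from .types import AnalysisConfig

_STUDY_TRAIT_MODELS = {"ShL": ((9.5, 6.0, 4.1), 1.0)}


def _study_recipe(seed: int, n_planted: int, effect_size_sd: float,
                  n_lines: int) -> SimulationRecipe:
    return SimulationRecipe(n_lines=n_lines, n_planted_qtl=n_planted,
                            effect_size_sd=effect_size_sd,
                            trait_models=dict(_STUDY_TRAIT_MODELS),
                            rng_seed=seed)


def _sim_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


@dataclass
class RecoveryStudy:
    n_sims: int
    effect_size_sd: float
    recovered: int
    false_calls: list[int]        # per-sim count of calls off the truth

    @property
    def recovery_percent(self) -> float:
        return 100.0 * self.recovered / self.n_sims

    @property
    def false_calls_per_sim(self) -> float:
        return float(np.mean(self.false_calls))

    @property
    def false_calls_se(self) -> float:
        return float(np.std(self.false_calls, ddof=1) / np.sqrt(self.n_sims))


@dataclass
class NullStudy:
    n_sims: int
    association_counts: list[int]  # per-sim associations of any class
    interaction_counts: list[int]  # per-sim interaction-class associations

    @property
    def associations_per_sim(self) -> float:
        return float(np.mean(self.association_counts))

    @property
    def associations_se(self) -> float:
        return float(np.std(self.association_counts, ddof=1)
                     / np.sqrt(self.n_sims))

    @property
    def interactions_per_sim(self) -> float:
        return float(np.mean(self.interaction_counts))

    @property
    def interactions_se(self) -> float:
        return float(np.std(self.interaction_counts, ddof=1)
                     / np.sqrt(self.n_sims))


def _scan_once(recipe: SimulationRecipe):
    lib, truth = simulate_library(recipe)
    phen = simulate_seedling_traits(recipe, lib, truth)
    config = AnalysisConfig(control_line_id=recipe.control_line_id,
                            treatments=recipe.treatments,
                            replicates=recipe.replicates)
    results = QtlScan(phen, lib, config, traits=["ShL"]).fit()
    return truth, results


def qtl_recovery_study(n_sims: int = 200, effect_size_sd: float = 2.5,
                       n_lines: int = 50, seed: int = 0) -> RecoveryStudy:
    """Planted-QTL recovery rate and off-target call counts."""
    recovered = 0
    false_calls = []
    for s in _sim_seeds(seed, n_sims):
        truth, results = _scan_once(
            _study_recipe(int(s), 1, effect_size_sd, n_lines))
        truth_iv = truth[0].interval
        hit = False
        off = 0
        for call in results.qtl_calls:
            if call.merged_interval.overlaps(truth_iv):
                hit = True
            else:
                off += 1
        recovered += hit
        false_calls.append(off)
    return RecoveryStudy(n_sims, effect_size_sd, recovered, false_calls)


def null_calibration_study(n_sims: int = 300, n_lines: int = 50,
                           seed: int = 0) -> NullStudy:
    """Association counts per library with no planted effects."""
    assoc_counts, inter_counts = [], []
    for s in _sim_seeds(seed, n_sims):
        _, results = _scan_once(_study_recipe(int(s), 0, 0.0, n_lines))
        assoc_counts.append(int(len(results.associations)))
        inter_counts.append(int(results.associations["is_interaction"].sum())
                            if len(results.associations) else 0)
    return NullStudy(n_sims, assoc_counts, inter_counts)


def expected_null_interaction_count(n_lines: int = 50, replicates: int = 3,
                                    n_treatments: int = 3,
                                    alpha: float = 0.01) -> float:
    """Closed-form expected interaction-class lines per null library.

    Within one treatment the family has k = n_lines comparisons on
    nu = (k + 1)(r - 1) error df; marginally t_i ~ t_nu, so the per-line
    per-context significance probability is q = P(|t_nu| > c_alpha) with
    c_alpha the Dunnett critical value.  Contexts are independent, hence
    P(exactly 1 or 2 of the 3 treatments significant) is binomial in q.
    """
    from .dunnett import critical_value

    k = n_lines
    df = (k + 1) * (replicates - 1)
    gammas = [np.sqrt(0.5)] * k
    c = critical_value(alpha, gammas, df)
    q = 2.0 * stats.t.sf(c, df)
    p12 = sum(stats.binom.pmf(j, n_treatments, q) for j in (1, 2))
    return n_lines * float(p12)
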