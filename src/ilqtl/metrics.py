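"""Germination and seedling trait metrics.

Germination kinetics are summarised per replicate box from daily counts of
newly germinated seeds N1..Nw over a w-day window (default 10):

* GP  -- germination percentage, 100 * sum(Nd) / seeds sown.
* GI  -- day-weighted germination index, sum((w + 1 - d) * Nd); early
  germination earns the largest weight (w on day 1 down to 1 on day w).
* MGT -- mean germination time, sum(d * Nd) / sum(Nd), in days.

These satisfy the identity MGT = w + 1 - GI / sum(Nd) whenever any seed
germinated.

Seedling traits are composed from measured primitives: total seedling length
SL = ShL + RL, root-shoot ratio RSR = RL / ShL, seed vigor index
SVI = GP * SL (GP in percent, SL in cm), water content percentage
WCP = 100 * (SFW - SDW) / SFW, seed viability percentage
SVP = 100 * stained / total.

Stress response is quantified by the stress tolerance index
STI = trait value under salt / trait value under control (dimensionless),
the treatment-vs-control reduction percentage R%, and the relative
performance RP% of a line against the recurrent parent.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import GerminationCounts

log = logging.getLogger("ilqtl")

#: primitive traits expected in a phenotype table before derivation
PRIMITIVE_TRAITS = ("GP", "GI", "MGT", "ShL", "RL", "SFW", "SDW")
DERIVED_TRAITS = ("SL", "RSR", "SVI", "WCP")

STI_TRAIT_NAMES = {"GP": "GPTI", "SL": "SLTI", "SFW": "SFWTI",
                   "SDW": "SDWTI", "WCP": "WCPTI"}


def germination_percentage(counts: GerminationCounts) -> float:
    """Percent of sown seeds that germinated within the window, in [0, 100]."""
    if counts.sown < 1:
        raise ValueError("sown must be >= 1")
    return 100.0 * counts.total_germinated / counts.sown


def germination_index(counts: GerminationCounts) -> float:
    """Sum over days d of (w + 1 - d) * Nd, weighting early germination up."""
    w = counts.window
    return float(sum((w + 1 - d) * n
                     for d, n in enumerate(counts.daily_counts, start=1)))


def mean_germination_time(counts: GerminationCounts) -> float:
    """Count-weighted mean day of germination; NaN if nothing germinated."""
    total = counts.total_germinated
    if total == 0:
        log.debug("no germination for %s/%s/rep%d; MGT undefined",
                  counts.line_id, counts.treatment, counts.replicate)
        return math.nan
    return sum(d * n for d, n in enumerate(counts.daily_counts, start=1)) / total


def germination_metrics_table(counts: Iterable[GerminationCounts]) -> pd.DataFrame:
    """Long-format GP/GI/MGT per (line, treatment, replicate)."""
    rows = []
    for c in counts:
        for trait, value in (("GP", germination_percentage(c)),
                             ("GI", germination_index(c)),
                             ("MGT", mean_germination_time(c))):
            rows.append({"line_id": c.line_id, "treatment": c.treatment,
                         "replicate": c.replicate, "trait": trait,
                         "value": value})
    return pd.DataFrame(rows,
                        columns=["line_id", "treatment", "replicate",
                                 "trait", "value"])


def seedling_length(shl: float, rl: float) -> float:
    return shl + rl


def root_shoot_ratio(shl: float, rl: float) -> float:
    if shl == 0 or math.isnan(shl):
        log.warning("RSR undefined for ShL = %s", shl)
        return math.nan
    return rl / shl


def seed_vigor_index(gp_percent: float, sl_cm: float) -> float:
    """GP (%) times total seedling length (cm); no rescaling."""
    return gp_percent * sl_cm


def water_content_percent(sfw: float, sdw: float) -> float:
    if sfw == 0 or math.isnan(sfw):
        log.warning("WCP undefined for SFW = %s", sfw)
        return math.nan
    return 100.0 * (sfw - sdw) / sfw


def seed_viability_percent(stained: int, total: int) -> float:
    if total < 1:
        raise ValueError("total seeds must be >= 1")
    return 100.0 * stained / total


def derived_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Append derived traits (SL, RSR, SVI, WCP) to a long phenotype table.

    Derivation happens per (line, treatment, replicate) from the primitives
    present in that cell; a missing primitive yields a missing derived value.
    """
    wide = table.pivot_table(index=["line_id", "treatment", "replicate"],
                             columns="trait", values="value", aggfunc="first")
    out = pd.DataFrame(index=wide.index)
    if {"ShL", "RL"} <= set(wide.columns):
        out["SL"] = wide["ShL"] + wide["RL"]
        shl = wide["ShL"].where(wide["ShL"] != 0)
        if (wide["ShL"] == 0).any():
            log.warning("ShL = 0 encountered; RSR set missing")
        out["RSR"] = wide["RL"] / shl
    if "GP" in wide.columns and "SL" in out.columns:
        out["SVI"] = wide["GP"] * out["SL"]
    if {"SFW", "SDW"} <= set(wide.columns):
        sfw = wide["SFW"].where(wide["SFW"] != 0)
        if (wide["SFW"] == 0).any():
            log.warning("SFW = 0 encountered; WCP set missing")
        out["WCP"] = 100.0 * (wide["SFW"] - wide["SDW"]) / sfw
    derived_long = (out.reset_index()
                    .melt(id_vars=["line_id", "treatment", "replicate"],
                          var_name="trait", value_name="value"))
    return pd.concat([table, derived_long[table.columns.tolist()]],
                     ignore_index=True)


def stress_tolerance_index(value_salt: float, value_control: float) -> float:
    """STI = value under salt / value under control; NaN if control <= 0."""
    if value_control <= 0 or math.isnan(value_control):
        log.warning("STI undefined for control value %s", value_control)
        return math.nan
    return value_salt / value_control


def sti_table(table: pd.DataFrame,
              traits: Sequence[str] = ("GP", "SL", "SFW", "SDW", "WCP"),
              control_treatment: str = "control") -> pd.DataFrame:
    """Per-replicate STI for each salt treatment against the control.

    STI is computed replicate-wise (salt replicate j over control replicate
    j of the same line) so that the ratios remain replicated observations
    amenable to ANOVA and Dunnett testing.  Output is a long phenotype table
    whose trait labels are e.g. ``SLTI`` and whose treatment labels name the
    salt level of the contrast.
    """
    sub = table[table["trait"].isin(traits)]
    wide = sub.pivot_table(index=["line_id", "replicate", "trait"],
                           columns="treatment", values="value", aggfunc="first")
    salt_levels = [t for t in wide.columns if t != control_treatment]
    ctrl = wide[control_treatment].where(wide[control_treatment] > 0)
    rows = []
    for salt in salt_levels:
        sti = wide[salt] / ctrl
        for (line_id, rep, trait), value in sti.items():
            rows.append({"line_id": line_id, "treatment": salt,
                         "replicate": rep,
                         "trait": STI_TRAIT_NAMES.get(trait, trait + "TI"),
                         "value": value})
    return pd.DataFrame(rows, columns=["line_id", "treatment", "replicate",
                                       "trait", "value"])


def reduction_percent(mean_treatment: float, mean_control: float) -> float:
    """R% = 100 * (treatment - control) / control; negative is a reduction."""
    if mean_control == 0 or math.isnan(mean_control):
        log.warning("R%% undefined for control mean %s", mean_control)
        return math.nan
    return 100.0 * (mean_treatment - mean_control) / mean_control


def relative_performance(lsm_il: float, lsm_control_line: float) -> float:
    """RP% = 100 * (LS-mean[IL] - LS-mean[control line]) / LS-mean[control line]."""
    if lsm_control_line == 0 or math.isnan(lsm_control_line):
        log.warning("RP%% undefined for control LS-mean %s", lsm_control_line)
        return math.nan
    return 100.0 * (lsm_il - lsm_control_line) / lsm_control_line
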