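"""End-to-end pipeline orchestration and plain-text report rendering.

`run_pipeline` chains simulate -> metrics -> anova -> qtl into one output
directory of TSVs plus a JSON run manifest (config snapshot, file checksums,
seed), so a run is reproducible byte-for-byte from its manifest inputs.
`render_summary` turns a completed run directory into a human-readable
report: per-trait ANOVA and heritability, means +- SE with reduction
percentages, the tolerance-index table, and the association table with
significance stars.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from pathlib import Path

import pandas as pd

from . import io as ilio
from . import metrics
from .anova import combined_anova, heritability, separate_anova
from .scan import QtlScan
from .simulate import SimulationRecipe, simulate_experiment, truth_table
from .types import AnalysisConfig

log = logging.getLogger("ilqtl")

STI_TRAITS = ("GPTI", "SLTI", "SFWTI", "SDWTI", "WCPTI")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(out_dir: str | os.PathLike,
                 recipe: SimulationRecipe | None = None,
                 config: AnalysisConfig | None = None) -> dict:
    """Simulate (or reuse) inputs, run every stage, write TSVs + manifest.

    Returns the manifest dict.  Stage failures propagate with the stage
    named in the log.
    """
    recipe = recipe or SimulationRecipe()
    config = config or AnalysisConfig(control_line_id=recipe.control_line_id,
                                      treatments=recipe.treatments,
                                      replicates=recipe.replicates,
                                      rng_seed=recipe.rng_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run: seed=%d out=%s", recipe.rng_seed, out)

    log.info("stage: simulate")
    sim = simulate_experiment(recipe)
    ilio.write_il_library(sim.library, out / "il_library.tsv")
    ilio.write_results(truth_table(sim.truth, recipe.treatments),
                       out / "truth.tsv")
    ilio.write_germination_counts(sim.germination,
                                  out / "germination_counts.tsv")

    log.info("stage: metrics")
    phen = sim.phenotypes
    sti = metrics.sti_table(phen, control_treatment=config.control_treatment)
    ilio.write_results(phen, out / "phenotypes.tsv")
    ilio.write_results(sti, out / "tolerance_indices.tsv")

    log.info("stage: anova")
    anova_rows, herit_rows = [], []
    traits = sorted(phen["trait"].unique())
    for trait in traits:
        for trt in config.treatments:
            try:
                res = separate_anova(phen, trait, trt)
            except ValueError:
                continue
            hb = heritability(res, config.replicates)
            anova_rows.append({
                "trait": trait, "model": "separate", "treatment": trt,
                "ms_g": res.terms.loc["G", "ms"],
                "F": res.terms.loc["G", "F"], "p": res.terms.loc["G", "p"],
                "cv_percent": res.cv_percent, "r_squared": res.r_squared})
            herit_rows.append({
                "trait": trait, "treatment": trt,
                "sigma2_g": hb.sigma2_g, "sigma2_e": hb.sigma2_e,
                "sigma2_p": hb.sigma2_p, "hb_percent": hb.hb_percent})
        try:
            comb = combined_anova(phen, trait)
        except ValueError:
            continue
        for term in ("G", "T", "G:T"):
            anova_rows.append({
                "trait": trait, "model": "combined", "treatment": term,
                "ms_g": comb.terms.loc[term, "ms"],
                "F": comb.terms.loc[term, "F"],
                "p": comb.terms.loc[term, "p"],
                "cv_percent": comb.cv_percent,
                "r_squared": comb.r_squared})
    ilio.write_results(pd.DataFrame(anova_rows), out / "anova.tsv")
    ilio.write_results(pd.DataFrame(herit_rows), out / "heritability.tsv")

    log.info("stage: qtl")
    scan_traits = [t for t in traits if t not in ("GI", "MGT")]
    results = QtlScan(phen, sim.library, config, traits=scan_traits).fit()
    ilio.write_results(results.association_table(), out / "associations.tsv")
    ilio.write_results(results.qtl_table(), out / "qtl_calls.tsv")

    sti_config = dataclasses.replace(config,
                                     treatments=tuple(config.treatments[1:]))
    sti_results = QtlScan(sti, sim.library, sti_config,
                          traits=sorted(sti["trait"].unique())).fit()
    ilio.write_results(sti_results.association_table(),
                       out / "sti_associations.tsv")
    ilio.write_results(sti_results.qtl_table(), out / "sti_qtl_calls.tsv")

    log.info("stage: report")
    (out / "report.txt").write_text(render_summary(out))

    manifest = {
        "rng_seed": recipe.rng_seed,
        "recipe": _jsonable(dataclasses.asdict(recipe)),
        "config": _jsonable(dataclasses.asdict(config)),
        "stages": ["simulate", "metrics", "anova", "qtl", "report"],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "checksums": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def means_table(phen: pd.DataFrame, control_treatment: str) -> pd.DataFrame:
    """Per-trait mean +- SE and range per treatment with R% vs control."""
    rows = []
    for trait, tgrp in phen.groupby("trait", sort=True):
        line_means = tgrp.groupby(["treatment", "line_id"])["value"].mean()
        row: dict = {"trait": trait}
        ctrl_mean = None
        for trt, grp in line_means.groupby(level="treatment", sort=False):
            m = grp.mean()
            se = grp.std(ddof=1) / len(grp) ** 0.5
            row[f"mean_{trt}"] = m
            row[f"se_{trt}"] = se
            row[f"range_{trt}"] = f"{grp.min():.1f}-{grp.max():.1f}"
            if trt == control_treatment:
                ctrl_mean = m
        if ctrl_mean is not None:
            for trt in line_means.index.get_level_values(0).unique():
                if trt != control_treatment:
                    row[f"r_percent_{trt}"] = metrics.reduction_percent(
                        row[f"mean_{trt}"], ctrl_mean)
        rows.append(row)
    return pd.DataFrame(rows)


def render_summary(results_dir: str | os.PathLike) -> str:
    """Render the plain-text report from a (possibly partial) run directory."""
    out = Path(results_dir)
    sections: list[str] = ["=== IL QTL scan report ==="]

    def _have(name: str) -> bool:
        return (out / name).exists()

    if _have("anova.tsv") and _have("heritability.tsv"):
        herit = pd.read_csv(out / "heritability.tsv", sep="\t")
        sections.append("\n--- Heritability (separate ANOVA) ---\n"
                        + herit.to_string(index=False))
    else:
        sections.append("\n[anova/heritability stage missing]")

    if _have("phenotypes.tsv"):
        phen = pd.read_csv(out / "phenotypes.tsv", sep="\t")
        treatments = list(dict.fromkeys(phen["treatment"]))
        tab = means_table(phen, treatments[0])
        fmt = {c: (lambda v: f"{v:.1f}") for c in tab.columns
               if c.startswith(("mean_", "se_", "r_percent_"))}
        sections.append("\n--- Trait means, SE, and reduction % ---\n"
                        + tab.to_string(index=False, formatters=fmt))

    if _have("tolerance_indices.tsv"):
        sti = pd.read_csv(out / "tolerance_indices.tsv", sep="\t")
        piv = sti.pivot_table(index="trait", columns="treatment",
                              values="value", aggfunc="mean")
        sections.append("\n--- Stress tolerance indices (means) ---\n"
                        + piv.to_string(float_format=lambda v: f"{v:.2f}"))

    for name, title in (("associations.tsv", "Trait associations"),
                        ("sti_associations.tsv",
                         "Tolerance-index associations")):
        if _have(name):
            try:
                assoc = pd.read_csv(out / name, sep="\t")
            except pd.errors.EmptyDataError:
                assoc = pd.DataFrame()
            if assoc.empty:
                sections.append(f"\n--- {title} ---\nzero associations")
            else:
                sections.append(f"\n--- {title} "
                                "(** p<0.01, * p<0.05, Dunnett-adjusted) ---\n"
                                + assoc.to_string(index=False))
    if _have("qtl_calls.tsv"):
        calls = pd.read_csv(out / "qtl_calls.tsv", sep="\t")
        sections.append(f"\n--- Putative QTL: {len(calls)} ---\n"
                        + (calls.to_string(index=False)
                           if len(calls) else "none"))
    return "\n".join(sections) + "\n"
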