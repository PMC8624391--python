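"""The QTL scan: Dunnett many-to-one tests, effect classification, merging.

`QtlScan` is the modelling entry point, built from a long-format phenotype
table, the IL library, and an `AnalysisConfig`; `.fit()` returns a
`QtlScanResults` carrying the per-comparison Dunnett table, the significant
line-by-trait associations, and the merged putative QTL calls.

The detection rule follows the many-to-one design of an IL library: every
line is compared to the recurrent parent with a Dunnett-adjusted t test,
within each treatment and on the treatment-pooled ("overall") values.  A
line x trait pair becomes an association when either

* interaction: the line differs from the parent (adjusted p < 0.01) in
  exactly one or two of the three treatments, or
* main effect: it differs (adjusted p < 0.05) in all three treatments or in
  the overall comparison

(thresholds configurable).  Associations on the same chromosome whose
introgression intervals overlap with agreeing effect signs are assumed to
carry the same QTL and are merged into a single named call spanning the
union of the member intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dunnett import DunnettOutcome, dunnett_many_to_one
from .metrics import relative_performance
from .types import AnalysisConfig, GeneticInterval, IntrogressionLine

OVERALL = "overall"


def ls_means(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """LS-means per (line, context); contexts are each treatment + overall.

    In the balanced completely-randomized design the LS-mean is the
    arithmetic mean over a line's replicates; the overall LS-mean averages
    over all treatments' replicates.  Missing replicates are averaged over
    whatever is available.
    """
    sub = table[table["trait"] == trait].dropna(subset=["value"])
    per_trt = (sub.groupby(["line_id", "treatment"])["value"].mean()
               .rename("ls_mean").reset_index()
               .rename(columns={"treatment": "context"}))
    overall = (sub.groupby("line_id")["value"].mean()
               .rename("ls_mean").reset_index())
    overall["context"] = OVERALL
    return pd.concat([per_trt, overall[per_trt.columns]], ignore_index=True)


def _context_samples(sub: pd.DataFrame, context: str,
                     treatments: Sequence[str]) -> pd.Series:
    """Per-line replicate vectors for one context.

    Treatment contexts use that treatment's replicates.  The overall context
    pools treatments per replicate: replicate j's value is the mean over
    treatments of that line's replicate-j observations (the replicate-level
    LS-mean over treatments), preserving r replicated values per line.
    """
    if context == OVERALL:
        pooled = (sub.groupby(["line_id", "replicate"])["value"].mean()
                  .reset_index())
        return pooled.groupby("line_id")["value"].apply(
            lambda s: s.to_numpy())
    cell = sub[sub["treatment"] == context]
    return cell.groupby("line_id")["value"].apply(lambda s: s.to_numpy())


def classify_effect(p_by_context: Mapping[str, float],
                    config: AnalysisConfig) -> tuple[bool, bool, bool]:
    """Apply the interaction / main-effect rule to one line x trait.

    Returns (is_interaction, is_main_effect, partial); ``partial`` flags a
    decision taken with at least one context's p-value missing.
    """
    trt_ps = {t: p_by_context.get(t, math.nan) for t in config.treatments}
    overall_p = p_by_context.get(OVERALL, math.nan)
    present = {t: p for t, p in trt_ps.items() if not math.isnan(p)}
    partial = (len(present) < len(config.treatments)
               or math.isnan(overall_p))
    n_sig_strict = sum(p < config.alpha_interaction for p in present.values())
    is_interaction = n_sig_strict in (1, 2)
    all_sig = (len(present) == len(config.treatments)
               and all(p < config.alpha_main for p in present.values()))
    overall_sig = (not math.isnan(overall_p)) and overall_p < config.alpha_main
    is_main = all_sig or overall_sig
    return is_interaction, is_main, partial


@dataclass(frozen=True)
class QtlCall:
    """One named putative QTL: a cluster of same-sign overlapping lines."""

    qtl_name: str
    trait: str
    chromosome: str
    merged_interval: GeneticInterval
    member_lines: tuple[str, ...]
    effect_sign: int
    contexts: tuple[str, ...]


class QtlScan:
    """Many-to-one QTL scan of an IL library against its recurrent parent.

    Parameters
    ----------
    phenotypes : DataFrame
        Long format (line_id, treatment, replicate, trait, value).
    library : sequence of IntrogressionLine
        The IL library; the control line must NOT appear in it.
    config : AnalysisConfig
        Thresholds, treatment set, control line id.
    traits : optional sequence of trait labels to scan (default: all traits
        present in the table).
    """

    def __init__(self, phenotypes: pd.DataFrame,
                 library: Sequence[IntrogressionLine],
                 config: AnalysisConfig,
                 traits: Sequence[str] | None = None):
        self.phenotypes = phenotypes
        self.library = list(library)
        self.config = config
        self.traits = (list(traits) if traits is not None
                       else sorted(phenotypes["trait"].unique()))
        self._by_id = {ln.line_id: ln for ln in self.library}
        if config.control_line_id in self._by_id:
            raise ValueError("control line must not be part of the IL library")
        if config.control_line_id not in set(phenotypes["line_id"]):
            raise ValueError(
                f"control line {config.control_line_id!r} absent from phenotypes")

    @classmethod
    def from_dataframe(cls, phenotypes: pd.DataFrame,
                       library: Sequence[IntrogressionLine],
                       config: AnalysisConfig | None = None,
                       **kwargs) -> "QtlScan":
        return cls(phenotypes, library, config or AnalysisConfig(), **kwargs)

    # ---------------------------------------------------------------- fit

    def fit(self) -> "QtlScanResults":
        cfg = self.config
        contexts = list(cfg.treatments) + [OVERALL]
        dunnett_rows: list[dict] = []
        for trait in self.traits:
            sub = self.phenotypes[self.phenotypes["trait"] == trait].dropna(
                subset=["value"])
            if sub.empty:
                continue
            for context in contexts:
                samples = _context_samples(sub, context, cfg.treatments)
                if cfg.control_line_id not in samples.index:
                    continue
                control = samples.loc[cfg.control_line_id]
                il_ids = [i for i in samples.index
                          if i != cfg.control_line_id and i in self._by_id]
                groups = [samples.loc[i] for i in il_ids]
                usable = [(i, g) for i, g in zip(il_ids, groups) if len(g) >= 2]
                if len(control) < 2 or not usable:
                    continue
                il_ids = [i for i, _ in usable]
                outcome = dunnett_many_to_one([g for _, g in usable], control)
                for j, line_id in enumerate(il_ids):
                    dunnett_rows.append({
                        "line_id": line_id, "trait": trait, "context": context,
                        "lsm_il": outcome.means[j],
                        "lsm_control": outcome.control_mean,
                        "t_statistic": outcome.t_statistics[j],
                        "p_adjusted": outcome.p_adjusted[j],
                        "rp_percent": relative_performance(
                            outcome.means[j], outcome.control_mean),
                    })
        dunnett_df = pd.DataFrame(
            dunnett_rows, columns=["line_id", "trait", "context", "lsm_il",
                                   "lsm_control", "t_statistic", "p_adjusted",
                                   "rp_percent"])
        assoc_df = self._classify(dunnett_df)
        calls = merge_to_qtl(assoc_df, self.library,
                             library_label=cfg.library_label)
        return QtlScanResults(self, dunnett_df, assoc_df, calls)

    def _classify(self, dunnett_df: pd.DataFrame) -> pd.DataFrame:
        cfg = self.config
        rows = []
        for (line_id, trait), grp in dunnett_df.groupby(["line_id", "trait"],
                                                        sort=True):
            p_by_ctx = dict(zip(grp["context"], grp["p_adjusted"]))
            is_int, is_main, partial = classify_effect(p_by_ctx, cfg)
            if not (is_int or is_main):
                continue
            sig = grp[grp["p_adjusted"] < cfg.alpha_main]
            signs = {int(np.sign(d)) for d in
                     (sig["lsm_il"] - sig["lsm_control"]) if d != 0}
            effect_sign = signs.pop() if len(signs) == 1 else 0
            line = self._by_id[line_id]
            rows.append({
                "line_id": line_id, "trait": trait,
                "chromosome": "+".join(line.chromosomes),
                "is_interaction": is_int, "is_main_effect": is_main,
                "partial": partial,
                "effect_sign": effect_sign,  # 0 = mixed signs
                "significant_contexts": ",".join(sig["context"]),
            })
        return pd.DataFrame(rows, columns=["line_id", "trait", "chromosome",
                                           "is_interaction", "is_main_effect",
                                           "partial", "effect_sign",
                                           "significant_contexts"])


# -------------------------------------------------------------- merging


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _trait_symbol(trait: str) -> str:
    return trait.capitalize()


def merge_to_qtl(associations: pd.DataFrame,
                 library: Sequence[IntrogressionLine],
                 library_label: str = "LIB") -> list[QtlCall]:
    """Cluster same-sign overlapping associations into named QTL calls.

    Per trait and chromosome, two associated lines join the same cluster iff
    some pair of their intervals overlaps (closed intervals; shared endpoint
    counts) AND their effect signs agree; mixed-sign associations (sign 0)
    never join.  Each connected component becomes one QtlCall spanning the
    union of member intervals, named ``Q<Trait>.<LIB>.<chr>`` with letter
    suffixes in merged-interval start order when a trait x chromosome has
    several calls.
    """
    by_id = {ln.line_id: ln for ln in library}
    calls: list[QtlCall] = []
    if associations.empty:
        return calls
    assoc = associations.sort_values(["trait", "line_id"]).reset_index(drop=True)
    for trait, tgrp in assoc.groupby("trait", sort=True):
        # explode per chromosome: a line with intervals on several
        # chromosomes yields one candidate per chromosome
        nodes: list[tuple[str, str, tuple[GeneticInterval, ...], int, str]] = []
        for _, row in tgrp.iterrows():
            line = by_id.get(row["line_id"])
            if line is None:
                warnings.warn(f"association line {row['line_id']!r} not in library")
                continue
            if len(line.chromosomes) > 1:
                warnings.warn(
                    f"line {line.line_id} has intervals on multiple "
                    "chromosomes; emitting one candidate per chromosome")
            for chrom in line.chromosomes:
                ivs = tuple(iv for iv in line.intervals
                            if iv.chromosome == chrom)
                nodes.append((line.line_id, chrom, ivs,
                              int(row["effect_sign"]),
                              row["significant_contexts"]))
        for chrom in sorted({n[1] for n in nodes}):
            cnodes = [n for n in nodes if n[1] == chrom]
            uf = _UnionFind(len(cnodes))
            for i in range(len(cnodes)):
                for j in range(i + 1, len(cnodes)):
                    si, sj = cnodes[i][3], cnodes[j][3]
                    if si == 0 or sj == 0 or si != sj:
                        continue
                    if any(a.overlaps(b) for a in cnodes[i][2]
                           for b in cnodes[j][2]):
                        uf.union(i, j)
            clusters: dict[int, list[int]] = {}
            for i in range(len(cnodes)):
                clusters.setdefault(uf.find(i), []).append(i)
            chrom_calls = []
            for members in clusters.values():
                ivs = [iv for m in members for iv in cnodes[m][2]]
                span = GeneticInterval(chrom, min(iv.start for iv in ivs),
                                       max(iv.end for iv in ivs))
                lines = tuple(sorted(cnodes[m][0] for m in members))
                signs = {cnodes[m][3] for m in members}
                sign = signs.pop() if len(signs) == 1 else 0
                ctxs = sorted({c for m in members
                               for c in cnodes[m][4].split(",") if c})
                chrom_calls.append((span, lines, sign, tuple(ctxs)))
            # suffixes ordered by merged start, then end, then first line id
            chrom_calls.sort(key=lambda c: (c[0].start, c[0].end, c[1][0]))
            many = len(chrom_calls) > 1
            for idx, (span, lines, sign, ctxs) in enumerate(chrom_calls):
                suffix = f".{chr(ord('a') + idx)}" if many else ""
                name = f"Q{_trait_symbol(trait)}.{library_label}.{chrom}{suffix}"
                calls.append(QtlCall(name, trait, chrom, span, lines, sign,
                                     ctxs))
    return calls


def validate_against_reference(calls: Sequence[QtlCall],
                               reference: pd.DataFrame) -> pd.DataFrame:
    """Overlap each call with a user-supplied reference QTL/marker list.

    ``reference`` needs columns chromosome and either position or
    start/end (cM); optional columns (trait, label, ...) are carried through.
    A reference entry corresponds to a call when it lies on the same
    chromosome and its position falls within (or its interval overlaps) the
    call's merged interval.
    """
    rows = []
    for call in calls:
        for _, ref in reference.iterrows():
            chrom = ref["chromosome"]
            if chrom not in {call.chromosome}:
                continue
            if "position" in reference.columns and not pd.isna(
                    ref.get("position", math.nan)):
                hit = call.merged_interval.contains(float(ref["position"]))
                where = f"{float(ref['position']):g}"
            elif {"start", "end"} <= set(reference.columns):
                try:
                    ref_iv = GeneticInterval(chrom, float(ref["start"]),
                                             float(ref["end"]))
                except ValueError:
                    warnings.warn(f"skipping malformed reference row {ref.to_dict()}")
                    continue
                hit = call.merged_interval.overlaps(ref_iv)
                where = f"{float(ref['start']):g}-{float(ref['end']):g}"
            else:
                raise ValueError("reference needs 'position' or 'start'/'end'")
            if hit:
                rows.append({"qtl_name": call.qtl_name, "trait": call.trait,
                             "chromosome": call.chromosome,
                             "call_interval": str(call.merged_interval),
                             "reference_position": where,
                             "reference_label": ref.get("label", "")})
    return pd.DataFrame(rows, columns=["qtl_name", "trait", "chromosome",
                                       "call_interval", "reference_position",
                                       "reference_label"])


# -------------------------------------------------------------- results


def _stars(p: float, alpha_main: float = 0.05,
           alpha_strict: float = 0.01) -> str:
    if math.isnan(p):
        return ""
    if p < alpha_strict:
        return "**"
    if p < alpha_main:
        return "*"
    return ""


@dataclass
class QtlScanResults:
    """Fitted scan: Dunnett table, associations, and merged QTL calls."""

    model: QtlScan
    dunnett: pd.DataFrame
    associations: pd.DataFrame
    qtl_calls: list[QtlCall] = field(default_factory=list)

    @property
    def n_associations(self) -> int:
        return len(self.associations)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_calls)

    def qtl_table(self) -> pd.DataFrame:
        rows = [{"qtl_name": c.qtl_name, "trait": c.trait,
                 "chromosome": c.chromosome,
                 "start_cM": c.merged_interval.start,
                 "end_cM": c.merged_interval.end,
                 "member_lines": ",".join(c.member_lines),
                 "effect_sign": c.effect_sign,
                 "contexts": ",".join(c.contexts)} for c in self.qtl_calls]
        return pd.DataFrame(rows, columns=["qtl_name", "trait", "chromosome",
                                           "start_cM", "end_cM",
                                           "member_lines", "effect_sign",
                                           "contexts"])

    def association_table(self) -> pd.DataFrame:
        """One row per association, columns in the per-line report layout:
        interval, per-context LS-mean, RP% and significance stars."""
        cfg = self.model.config
        by_id = self.model._by_id
        rows = []
        for _, a in self.associations.iterrows():
            line = by_id[a["line_id"]]
            row = {"trait": a["trait"], "line_id": a["line_id"],
                   "chromosome": a["chromosome"],
                   "interval_cM": ";".join(f"{iv.start:g}-{iv.end:g}"
                                           for iv in line.intervals),
                   "is_interaction": a["is_interaction"],
                   "is_main_effect": a["is_main_effect"],
                   "effect_sign": a["effect_sign"]}
            sub = self.dunnett[(self.dunnett["line_id"] == a["line_id"])
                               & (self.dunnett["trait"] == a["trait"])]
            for ctx in list(cfg.treatments) + [OVERALL]:
                hit = sub[sub["context"] == ctx]
                if hit.empty:
                    continue
                r = hit.iloc[0]
                row[f"lsm_{ctx}"] = r["lsm_il"]
                row[f"rp_{ctx}"] = r["rp_percent"]
                row[f"sig_{ctx}"] = _stars(r["p_adjusted"], cfg.alpha_main,
                                           cfg.alpha_interaction)
            rows.append(row)
        base_cols = ["trait", "line_id", "chromosome", "interval_cM",
                     "is_interaction", "is_main_effect", "effect_sign"]
        return pd.DataFrame(rows, columns=base_cols if not rows else None)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "QTL scan: Dunnett many-to-one vs "
            f"{cfg.control_line_id} ({len(self.model.library)} lines, "
            f"{len(self.model.traits)} traits)",
            f"associations: {self.n_associations}   "
            f"putative QTL: {self.n_qtl}",
        ]
        if self.n_qtl:
            lines.append(self.qtl_table().to_string(index=False))
        return "\n".join(lines)
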