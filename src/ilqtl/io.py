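"""Tabular readers/writers and configuration loading.

All interchange is tab-separated text.  Phenotypes travel long-format
(line_id, treatment, replicate, trait, value); the IL library is one row per
introgression interval.  Writing uses a fixed column order and fixed numeric
formatting (1 decimal for means/percentages, 2 for indices, 4 for p-values)
so outputs diff cleanly and round-trip through the readers.
"""

from __future__ import annotations

import logging
import os
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .types import (
    AnalysisConfig,
    GeneticInterval,
    GerminationCounts,
    IntrogressionLine,
    ValidationError,
    check_library,
)

log = logging.getLogger("ilqtl")

PHENOTYPE_COLUMNS = ["line_id", "treatment", "replicate", "trait", "value"]

#: decimals used when serialising a column, by name; anything else gets 4.
_COLUMN_DECIMALS = {
    "mean": 1, "lsm_il": 1, "lsm_control": 1, "rp_percent": 1,
    "reduction_percent": 1, "cv_percent": 1, "hb_percent": 1,
    "sti": 2, "value": 4, "p": 4, "p_adjusted": 4, "t_statistic": 4,
    "start_cM": 1, "end_cM": 1, "start": 1, "end": 1,
}


class ParseError(ValueError):
    """A malformed input row; the message names the offending line number."""


def read_il_library(path: str | os.PathLike,
                    chromosomes: Sequence[str] | None = None,
                    ) -> list[IntrogressionLine]:
    """Read an IL library TSV (line_id, chromosome, start_cM, end_cM).

    Rows are grouped by ``line_id`` preserving file order; a line may carry
    several intervals.  Interval invariants (start <= end, start >= 0) are
    enforced per row.
    """
    intervals: dict[str, list[GeneticInterval]] = {}
    with open(path) as fh:
        header = fh.readline()
        if header and not header.rstrip("\n").split("\t")[0] == "line_id":
            raise ParseError(f"{path}: first column must be 'line_id', got {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            line_id, chrom, s_start, s_end = parts
            try:
                start, end = float(s_start), float(s_end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric map position") from exc
            try:
                iv = GeneticInterval(chrom, start, end)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            intervals.setdefault(line_id, []).append(iv)
    library = [IntrogressionLine(lid, tuple(ivs)) for lid, ivs in intervals.items()]
    if not library:
        log.warning("empty IL library read from %s", path)
    check_library(library, chromosomes)
    return library


def write_il_library(library: Sequence[IntrogressionLine],
                     path: str | os.PathLike) -> None:
    rows = [
        {"line_id": ln.line_id, "chromosome": iv.chromosome,
         "start_cM": iv.start, "end_cM": iv.end}
        for ln in library for iv in ln.intervals
    ]
    write_results(pd.DataFrame(rows, columns=["line_id", "chromosome",
                                              "start_cM", "end_cM"]), path)


def read_phenotypes(path: str | os.PathLike,
                    treatments: Sequence[str] | None = None,
                    traits: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a long-format phenotype TSV into a validated DataFrame.

    ``NA`` (or empty) values become missing, not errors.  Duplicate
    (line, treatment, replicate, trait) keys and labels outside the declared
    treatment/trait sets are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "treatment": str,
                                            "trait": str})
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    df = df[PHENOTYPE_COLUMNS]
    try:
        df["replicate"] = df["replicate"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-integer replicate label") from exc
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    bad = pd.read_csv(path, sep="\t")["value"].astype(str).str.strip()
    unparsed = df["value"].isna() & ~bad.isin(["NA", "", "nan", "NaN"])
    if unparsed.any():
        first = int(unparsed.idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}:{first}: non-numeric trait value")
    if treatments is not None:
        unknown = set(df["treatment"]) - set(treatments)
        if unknown:
            raise ValidationError(f"{path}: unknown treatment labels {sorted(unknown)}")
    if traits is not None:
        unknown = set(df["trait"]) - set(traits)
        if unknown:
            raise ValidationError(f"{path}: unknown trait labels {sorted(unknown)}")
    key = ["line_id", "treatment", "replicate", "trait"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValidationError(
            f"{path}: {int(dup.sum())} duplicate (line, treatment, replicate, trait) keys"
        )
    return df.reset_index(drop=True)


def read_germination_counts(path: str | os.PathLike) -> list[GerminationCounts]:
    """Read daily germination counts (columns sown, day1..dayW)."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "treatment": str})
    day_cols = [c for c in df.columns if c.startswith("day")]
    day_cols.sort(key=lambda c: int(c[3:]))
    out = []
    for _, row in df.iterrows():
        out.append(GerminationCounts(
            line_id=row["line_id"], treatment=row["treatment"],
            replicate=int(row["replicate"]), sown=int(row["sown"]),
            daily_counts=tuple(int(row[c]) for c in day_cols),
        ))
    return out


def write_germination_counts(counts: Sequence[GerminationCounts],
                             path: str | os.PathLike) -> None:
    if counts:
        window = counts[0].window
    else:
        window = 10
    rows = []
    for c in counts:
        row = {"line_id": c.line_id, "treatment": c.treatment,
               "replicate": c.replicate, "sown": c.sown}
        row.update({f"day{d}": c.daily_counts[d - 1] for d in range(1, window + 1)})
        rows.append(row)
    cols = ["line_id", "treatment", "replicate", "sown"] + [
        f"day{d}" for d in range(1, window + 1)]
    write_results(pd.DataFrame(rows, columns=cols), path)


def write_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Serialise a result table deterministically (fixed formatting)."""
    df = table.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            dec = _COLUMN_DECIMALS.get(col, 4)
            df[col] = df[col].map(
                lambda v, d=dec: "" if pd.isna(v) else f"{v:.{d}f}")
    df.to_csv(path, sep="\t", index=False)


def load_config(path: str | os.PathLike) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML (or JSON) mapping."""
    with open(path) as fh:
        raw: Mapping = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    for tuple_field in ("treatments", "chromosomes"):
        if tuple_field in kwargs:
            kwargs[tuple_field] = tuple(kwargs[tuple_field])
    return AnalysisConfig(**kwargs)
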