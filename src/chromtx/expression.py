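"""Expression quantification: TSS tag counting, RPM scaling, aggregation, replicates.

Two quantification routes are supported, mirroring how 5'-tag techniques
(CAGE, RNA-PET) and transcript-level techniques (RNA-Seq RPKM tables) measure
expression:

* tag route — count tag 5' ends in a 101 bp window centered on each TSS and
  normalize to reads per million (RPM);
* transcript route — sum per-transcript RPKM over the transcripts sharing a
  TSS (the upstream quantifier already assigns each read to one transcript).

Replicates of the same experiment are merged by per-gene arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TssSite

__all__ = [
    "ExpressionTable",
    "TagSet",
    "read_tags",
    "quantify_tss_from_tags",
    "rpm_normalize",
    "aggregate_tx_to_tss",
    "merge_replicates",
]

#: metadata keys that must agree between replicates of one experiment
_EXPERIMENT_KEYS = ("technique", "rna_fraction", "compartment", "cell_line")


@dataclass
class ExpressionTable:
    """Per-gene (or per-TSS) expression values plus experiment metadata."""

    values: pd.Series  # index: gene/TSS ids, values >= 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("expression ids must be unique")
        if (self.values < 0).any():
            raise ValueError("expression values must be >= 0")

    @property
    def ids(self) -> pd.Index:
        return self.values.index

    def to_tsv(self, path) -> None:
        self.values.rename("value").rename_axis("id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, **metadata) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        return cls(pd.Series(df["value"].values, index=df["id"].values), metadata)


@dataclass
class TagSet:
    """Mapped tag 5' positions and the library size they came from."""

    tags: pd.DataFrame  # columns: chrom, pos, strand
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size < len(self.tags):
            raise ValueError("library_size must be >= number of stored tags")


def read_tags(path, format: str = "bed6", library_size: int | None = None) -> TagSet:
    """Load tag 5' ends from BED6 (5' end = start for +, end-1 for -) or TSV.

    TSV format is two or three columns: position, strand[, chrom].  When
    ``library_size`` is omitted the number of tags in the file is used.
    """
    path = Path(path)
    if format == "bed6":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=[0, 1, 2, 5],
        )
        pos = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        tags = pd.DataFrame({"chrom": df["chrom"], "pos": pos, "strand": df["strand"]})
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        tags = pd.DataFrame(
            {
                "chrom": df.get("chrom", "chr1"),
                "pos": df["position"],
                "strand": df["strand"],
            }
        )
    else:
        raise ValueError(f"unknown tag format {format!r}")
    return TagSet(tags, library_size if library_size is not None else len(tags))


def quantify_tss_from_tags(
    tags: TagSet,
    sites: Sequence[TssSite],
    window_bp: int = 101,
    stranded: bool = False,
) -> pd.Series:
    """Count tag 5' ends in the ``window_bp`` window centered on each TSS.

    The window covers ``[position - (w-1)/2, position + (w-1)/2]`` inclusive on
    both ends, so a 101 bp window spans exactly +/-50 bp.  ``window_bp`` must
    be odd.  With ``stranded=True`` only tags on the TSS strand are counted.
    """
    if window_bp % 2 == 0:
        raise ValueError("window_bp must be odd so the window centers on the TSS")
    half = (window_bp - 1) // 2
    counts = {}
    by_chrom: dict[tuple, np.ndarray] = {}
    for key, grp in tags.tags.groupby(["chrom", "strand"] if stranded else ["chrom"]):
        by_chrom[key] = np.sort(grp["pos"].to_numpy())
    for site in sites:
        key = (site.chrom, site.strand) if stranded else (site.chrom,)
        pos = by_chrom.get(key)
        if pos is None:
            counts[site.site_id] = 0
            continue
        lo = np.searchsorted(pos, site.position - half, side="left")
        hi = np.searchsorted(pos, site.position + half, side="right")
        counts[site.site_id] = int(hi - lo)
    return pd.Series(counts, dtype=int)


def rpm_normalize(counts: pd.Series, library_size: int, **metadata) -> ExpressionTable:
    """Reads-per-million scaling: ``count / library_size * 1e6``."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return ExpressionTable(counts.astype(float) / library_size * 1e6, dict(metadata))


def aggregate_tx_to_tss(
    tx_levels: Mapping[str, float] | pd.Series,
    sites: Sequence[TssSite],
    **metadata,
) -> ExpressionTable:
    """Sum per-transcript quantification (RPKM) over each TSS's member transcripts."""
    levels = pd.Series(tx_levels, dtype=float)
    values = {}
    missing: list[str] = []
    for site in sites:
        members = sorted(site.member_transcripts)
        absent = [m for m in members if m not in levels.index]
        if absent:
            missing.extend(absent)
            continue
        values[site.site_id] = float(levels[members].sum())
    if missing:
        raise KeyError(f"transcripts missing from quantification table: {sorted(set(missing))}")
    return ExpressionTable(pd.Series(values, dtype=float), dict(metadata))


def merge_replicates(tables: Sequence[ExpressionTable]) -> ExpressionTable:
    """Average replicate measurements gene-by-gene.

    All tables must cover the identical id set and agree on experiment
    metadata (technique, RNA fraction, compartment, cell line); a replicate
    index may differ.
    """
    if not tables:
        raise ValueError("need at least one table")
    first = tables[0]
    ref_ids = set(first.ids)
    for t in tables[1:]:
        if set(t.ids) != ref_ids:
            raise ValueError("replicates cover different id sets")
        for key in _EXPERIMENT_KEYS:
            if t.metadata.get(key) != first.metadata.get(key):
                raise ValueError(
                    f"replicates disagree on metadata {key!r}: "
                    f"{t.metadata.get(key)!r} vs {first.metadata.get(key)!r}"
                )
    stacked = pd.concat([t.values.reindex(first.ids) for t in tables], axis=1)
    meta = {k: v for k, v in first.metadata.items() if k != "replicate"}
    meta["n_replicates"] = len(tables)
    return ExpressionTable(stacked.mean(axis=1), meta)
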