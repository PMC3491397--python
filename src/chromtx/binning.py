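"""Bin layouts over extended gene models and per-bin signal summarization.

A transcript longer than 4,100 bp is extended by 2,000 bp on each side and cut
into 81 bins: 40 bins of 100 bp across the [-2k, +2k] TSS flank, one bin for
the remaining gene body, and 40 bins of 100 bp across the [-2k, +2k] TTS
flank.  Bins are ordered 5'->3' along the transcript, so minus-strand layouts
run in decreasing genome coordinates.  TSS-anchored expression (CAGE-like)
uses the 41-bin variant: the 40 TSS-flank bins plus the body bin.

Per-bin values are base-weighted mean signal with uncovered bases counted as
zero (the "mean0" convention: absent ChIP signal is biologically zero, and it
keeps every bin defined).

The representative value of a feature is then chosen by one of four
strategies: ``bestbin`` (the single bin whose signal correlates most strongly,
in absolute value, with expression), ``best5bins`` (mean of the top five such
bins), ``tssbin`` (mean of the 40 TSS-flank bins — the fixed-window strategy of
earlier work), or ``allbins`` (mean over the whole layout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TranscriptRecord
from .transforms import GRID_FLOOR_FRACTION, pearson_r

__all__ = [
    "BinLayout",
    "BinnedFeatureMatrix",
    "BinSpec",
    "BedGraphTrack",
    "BigWigTrack",
    "read_track",
    "build_bin_layout",
    "summarize_track",
    "select_bin_spec",
    "apply_bin_spec",
    "TX81_BINS",
    "TSS41_BINS",
    "FLANK_BP",
    "FLANK_BINS",
]

FLANK_BP = 2000
FLANK_BINS = 40
TX81_BINS = 2 * FLANK_BINS + 1
TSS41_BINS = FLANK_BINS + 1

_STRATEGIES = ("bestbin", "best5bins", "tssbin", "allbins")


@dataclass
class BinLayout:
    """Ordered genomic intervals of one transcript's bins (5'->3')."""

    transcript_id: str
    chrom: str
    strand: str
    mode: str
    bins: np.ndarray  # shape (n_bins, 2); each row (start, end) with start < end

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def to_bed(self) -> str:
        lines = []
        for i, (s, e) in enumerate(self.bins):
            lines.append(
                f"{self.chrom}\t{s}\t{e}\t{self.transcript_id}.bin{i}\t0\t{self.strand}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class BinnedFeatureMatrix:
    """Genes x bins mean-signal matrix for one chromatin feature."""

    feature_name: str
    values: pd.DataFrame  # index: gene ids; columns: bin indices 0..n_bins-1

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("binned signal must be finite")

    def to_tsv(self, path) -> None:
        self.values.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, feature_name: str = "") -> "BinnedFeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        df.columns = [int(c) for c in df.columns]
        return cls(feature_name or Path(path).stem, df)


@dataclass
class BinSpec:
    """Which bin(s) summarize a feature, and the correlation that chose them."""

    feature_name: str
    strategy: str
    selected_bins: list[int]
    selection_correlation: float = float("nan")

    def __post_init__(self) -> None:
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not self.selected_bins:
            raise ValueError("selected_bins must be non-empty")
        if self.strategy == "bestbin" and len(self.selected_bins) != 1:
            raise ValueError("bestbin selects exactly one bin")
        if self.strategy == "best5bins" and len(self.selected_bins) != 5:
            raise ValueError("best5bins selects exactly five bins")


def build_bin_layout(
    tx: TranscriptRecord,
    mode: str = "tx81",
    flank_bp: int = FLANK_BP,
    flank_bins: int = FLANK_BINS,
) -> BinLayout:
    """Build the 81-bin (tx81) or 41-bin (tss41) layout for one transcript.

    The layout tiles [TSS - flank, TTS + flank] in transcript orientation with
    no gaps: ``flank_bins`` equal bins over each flank and a single body bin
    between them.  The transcript must be longer than ``2 * flank_bp + 100``
    so the body bin is non-empty.
    """
    if mode not in ("tx81", "tss41"):
        raise ValueError(f"unknown layout mode {mode!r}")
    min_len = 2 * flank_bp + 100
    if tx.length <= min_len:
        raise ValueError(
            f"transcript {tx.transcript_id} (length {tx.length}) too short for the "
            f"{mode} layout; needs length > {min_len}"
        )
    bw = 2 * flank_bp // flank_bins  # 100 bp at the defaults
    sign = 1 if tx.strand == "+" else -1
    tss, tts = tx.tss, tx.tts

    def flank(anchor: int) -> list[tuple[int, int]]:
        """flank_bins equal bins tiling [anchor - flank, anchor + flank], 5'->3'."""
        out = []
        for i in range(flank_bins):
            a = anchor + sign * (-flank_bp + i * bw)
            b = a + sign * bw
            out.append((min(a, b), max(a, b)))
        return out

    body = tuple(sorted((tss + sign * flank_bp, tts - sign * flank_bp)))
    if mode == "tx81":
        bins = flank(tss) + [body] + flank(tts)
    else:  # tss41: the TSS flank plus the body bin
        bins = flank(tss) + [body]
    return BinLayout(tx.transcript_id, tx.chrom, tx.strand, mode, np.asarray(bins))


class BedGraphTrack:
    """Per-base signal backed by a (sorted, non-overlapping) bedGraph file."""

    def __init__(self, path):
        starts: dict[str, list] = {}
        ends: dict[str, list] = {}
        vals: dict[str, list] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise ValueError(f"bedGraph line {lineno}: expected 4 columns")
                chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                starts.setdefault(chrom, []).append(s)
                ends.setdefault(chrom, []).append(e)
                vals.setdefault(chrom, []).append(v)
        self._chroms = {}
        for chrom in starts:
            s = np.asarray(starts[chrom])
            e = np.asarray(ends[chrom])
            v = np.asarray(vals[chrom])
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            # prefix sums of covered signal, for O(log n) interval sums
            cum = np.concatenate([[0.0], np.cumsum(v * (e - s))])
            self._chroms[chrom] = (s, e, v, cum)

    @property
    def chroms(self):
        return list(self._chroms)

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base signal over [start, end); uncovered bases add 0."""
        if chrom not in self._chroms:
            raise KeyError(f"chromosome {chrom!r} absent from track")
        s, e, v, cum = self._chroms[chrom]
        i0 = int(np.searchsorted(e, start, side="right"))
        i1 = int(np.searchsorted(s, end, side="left"))
        if i0 >= i1:
            return 0.0
        total = cum[i1] - cum[i0]
        total -= v[i0] * max(0, start - s[i0])
        total -= v[i1 - 1] * max(0, e[i1 - 1] - end)
        return float(total)


class BigWigTrack:
    """Same protocol as :class:`BedGraphTrack`, backed by a bigWig file."""

    def __init__(self, path):
        import pyBigWig

        self._bw = pyBigWig.open(str(path))

    @property
    def chroms(self):
        return list(self._bw.chroms())

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self._bw.chroms():
            raise KeyError(f"chromosome {chrom!r} absent from track")
        out = self._bw.stats(chrom, int(start), int(end), type="sum", exact=True)[0]
        return float(out) if out is not None else 0.0


def read_track(path):
    """Open a signal track: .bw/.bigwig via pyBigWig, anything else as bedGraph."""
    p = Path(path)
    if p.suffix.lower() in (".bw", ".bigwig"):
        return BigWigTrack(p)
    return BedGraphTrack(p)


def summarize_track(track, layout: BinLayout) -> np.ndarray:
    """Per-bin mean signal density, counting uncovered bases as zero.

    This is the "mean0" summarization: each bin's value is (sum of per-base
    signal over the bin) / (bin width), so bins with no track coverage are 0
    rather than missing.
    """
    means = np.empty(layout.n_bins)
    for i, (s, e) in enumerate(layout.bins):
        width = int(e) - int(s)
        means[i] = track.interval_sum(layout.chrom, int(s), int(e)) / width
    return means


def _selection_log(values: np.ndarray) -> np.ndarray:
    """Provisional log transform used while scanning for the best bin.

    Bin selection happens before the per-feature pseudocount exists, so a
    small floor proportional to the matrix maximum stands in for it.
    """
    vmax = float(values.max())
    if vmax <= 0:
        return values.astype(float)
    return np.log2(values + GRID_FLOOR_FRACTION * vmax)


def select_bin_spec(
    binned: BinnedFeatureMatrix | pd.DataFrame,
    y_log: np.ndarray | pd.Series,
    strategy: str = "bestbin",
) -> BinSpec:
    """Choose the summary bin(s) of a feature on the selection set (D1).

    ``bestbin`` picks the single bin with the highest absolute Pearson
    correlation between (provisionally log-transformed) bin signal and log2
    expression; ``best5bins`` the top five such bins; ``tssbin`` always uses
    the 40 TSS-flank bins; ``allbins`` the whole layout.  Zero-variance bins
    count as correlation 0 and ties break toward the lowest bin index.
    """
    if isinstance(binned, BinnedFeatureMatrix):
        name, df = binned.feature_name, binned.values
    else:
        name, df = "", binned
    if len(df) < 3:
        raise ValueError("need at least 3 genes to select bins")
    y_log = np.asarray(y_log, dtype=float)
    if len(y_log) != len(df):
        raise ValueError("y_log length must match the number of genes")
    X = _selection_log(df.to_numpy())
    n_bins = X.shape[1]
    corrs = np.array([pearson_r(X[:, j], y_log) for j in range(n_bins)])

    if strategy == "tssbin":
        sel = list(range(FLANK_BINS)) if n_bins > FLANK_BINS else list(range(n_bins))
    elif strategy == "allbins":
        sel = list(range(n_bins))
    elif strategy == "bestbin":
        sel = [int(np.argmax(np.abs(corrs)))]  # argmax takes the lowest index on ties
    elif strategy == "best5bins":
        # sort by (-|r|, index): strongest first, ties toward lower index
        order = sorted(range(n_bins), key=lambda j: (-abs(corrs[j]), j))
        sel = order[:5]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    summary = X[:, sel].mean(axis=1)
    return BinSpec(name, strategy, sel, pearson_r(summary, y_log))


def apply_bin_spec(
    binned: BinnedFeatureMatrix | pd.DataFrame, spec: BinSpec
) -> pd.Series:
    """Collapse a genes x bins matrix to one value per gene using a BinSpec.

    Bestbin returns the selected bin's raw signal; multi-bin strategies return
    the mean across the selected bins.
    """
    df = binned.values if isinstance(binned, BinnedFeatureMatrix) else binned
    n_bins = df.shape[1]
    bad = [b for b in spec.selected_bins if b < 0 or b >= n_bins]
    if bad:
        raise IndexError(f"bin indices {bad} out of range for {n_bins}-bin matrix")
    return df.iloc[:, spec.selected_bins].mean(axis=1)
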