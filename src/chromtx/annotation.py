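"""Gene-model I/O: transcripts, TSS derivation, representative picking, CpG class.

Internally all coordinates are 0-based half-open (BED convention); GTF input
(1-based inclusive) is converted on read.  The TSS of a transcript is its most
5' boundary: ``start`` on the plus strand and ``end`` on the minus strand.
Promoters are classified as high- or low-CpG (HCP/LCP) by the normalized CpG
content of the +/-1,500 bp region around the TSS, thresholded at 0.4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TranscriptRecord",
    "TssSite",
    "PromoterClass",
    "read_transcript_annotation",
    "derive_tss_sites",
    "filter_by_length",
    "select_representative",
    "normalized_cpg_score",
    "cpg_score_from_sequence",
    "HCP_THRESHOLD",
    "MIN_TRANSCRIPT_LENGTH",
]

HCP_THRESHOLD = 0.4
#: transcripts must be strictly longer than this to support the 81-bin layout
MIN_TRANSCRIPT_LENGTH = 4100

#: GTF attribute markers indicating the coding sequence 5' end is not defined
_INCOMPLETE_5P_TAGS = ("cds_start_NF", "CDS start not found")


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript with strand-oriented TSS/TTS."""

    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_incomplete_5p: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.transcript_id}")
        if not self.start < self.end:
            raise ValueError(f"start must be < end for {self.transcript_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class TssSite:
    """A unique (chrom, position, strand) transcription start site.

    A single TSS can be shared by several transcripts of the same gene (or of
    different genes), so the site keeps the ids of all member transcripts.
    """

    chrom: str
    position: int
    strand: str
    member_transcripts: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.member_transcripts:
            raise ValueError("a TSS site must have at least one member transcript")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.position}:{self.strand}"


@dataclass(frozen=True)
class PromoterClass:
    """Normalized CpG score of a promoter and its HCP/LCP label."""

    gene_id: str
    cpg_score: float
    label: str

    def __post_init__(self) -> None:
        if self.label != ("HCP" if self.cpg_score > HCP_THRESHOLD else "LCP"):
            raise ValueError("label inconsistent with cpg_score and 0.4 threshold")


def _parse_gtf(path: Path) -> list[TranscriptRecord]:
    from gffutils.feature import feature_from_line

    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with position
                raise ValueError(f"unparsable GTF line {lineno} in {path}: {exc}") from exc
            if feat.featuretype != "transcript":
                continue
            if feat.strand not in ("+", "-"):
                raise ValueError(
                    f"line {lineno} in {path}: unknown strand {feat.strand!r}"
                )
            attrs = feat.attributes
            try:
                tx_id = attrs["transcript_id"][0]
                gene_id = attrs["gene_id"][0]
            except KeyError as exc:
                raise ValueError(
                    f"line {lineno} in {path}: missing {exc} attribute"
                ) from exc
            tags = attrs.get("tag", [])
            incomplete = any(
                marker in tag for tag in tags for marker in _INCOMPLETE_5P_TAGS
            )
            records.append(
                TranscriptRecord(
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    chrom=feat.seqid,
                    start=feat.start - 1,  # GTF is 1-based inclusive
                    end=feat.end,
                    strand=feat.strand,
                    cds_incomplete_5p=incomplete,
                )
            )
    return records


def _parse_bed12(path: Path) -> list[TranscriptRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"line {lineno} in {path}: BED12 needs 12 columns, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"line {lineno} in {path}: unknown strand {strand!r}"
                )
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"line {lineno} in {path}: {exc}") from exc
            # BED has no gene grouping; the name doubles as both ids
            records.append(
                TranscriptRecord(
                    transcript_id=name,
                    gene_id=name,
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                )
            )
    return records


def read_transcript_annotation(path, format: str | None = None) -> list[TranscriptRecord]:
    """Read transcripts from GTF or BED12.

    ``format`` is ``"GTF"`` or ``"BED12"``; when omitted it is inferred from
    the file extension.  GTF ``tag`` attributes containing ``cds_start_NF`` or
    ``CDS start not found`` set the 5'-incompleteness flag.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "GTF" if suffix in (".gtf", ".gff") else "BED12"
    format = format.upper()
    if format == "GTF":
        return _parse_gtf(path)
    if format == "BED12":
        return _parse_bed12(path)
    raise ValueError(f"unknown annotation format {format!r}")


def derive_tss_sites(transcripts: Iterable[TranscriptRecord]) -> list[TssSite]:
    """Group transcripts with a defined 5' end into unique TSS sites.

    Transcripts flagged ``cds_incomplete_5p`` are excluded: their annotated 5'
    terminus is not trustworthy as a start site.
    """
    groups: dict[tuple[str, int, str], set[str]] = {}
    for tx in transcripts:
        if tx.cds_incomplete_5p:
            continue
        groups.setdefault((tx.chrom, tx.tss, tx.strand), set()).add(tx.transcript_id)
    return [
        TssSite(chrom, pos, strand, frozenset(members))
        for (chrom, pos, strand), members in sorted(groups.items())
    ]


def filter_by_length(
    transcripts: Iterable[TranscriptRecord], min_length_bp: int = MIN_TRANSCRIPT_LENGTH
) -> list[TranscriptRecord]:
    """Keep transcripts strictly longer than ``min_length_bp``.

    The default 4,100 bp is the minimum gene length for which the 81-bin
    layout (two 2,000 bp flanks plus a non-empty body bin) is defined.
    """
    if min_length_bp < 0:
        raise ValueError("min_length_bp must be >= 0")
    return [tx for tx in transcripts if tx.length > min_length_bp]


def select_representative(
    gene_transcripts: Sequence[TranscriptRecord], expression: Mapping[str, float]
) -> TranscriptRecord:
    """Pick the most highly expressed transcript as the gene's representative.

    Ties break toward the lexicographically smallest transcript_id so the
    choice is deterministic.
    """
    if not gene_transcripts:
        raise ValueError("need at least one transcript")
    missing = [t.transcript_id for t in gene_transcripts if t.transcript_id not in expression]
    if missing:
        raise KeyError(f"no expression value for transcripts: {sorted(missing)}")
    return min(
        gene_transcripts,
        key=lambda t: (-float(expression[t.transcript_id]), t.transcript_id),
    )


def cpg_score_from_sequence(seq: str, formula: str = "obs_exp") -> float:
    """Normalized CpG content of a sequence region.

    ``obs_exp`` (default) is the observed/expected ratio
    ``#CG * L / (#C * #G)``; ``gc`` uses the expected value derived from total
    GC content, ``(#CG / L) / ((GC / 2)^2)``.  Both are case-insensitive and
    return 0 when the expected count is 0.
    """
    s = seq.upper()
    L = len(s)
    if L == 0:
        return 0.0
    n_c = s.count("C")
    n_g = s.count("G")
    n_cg = s.count("CG")
    if formula == "obs_exp":
        if n_c == 0 or n_g == 0:
            return 0.0
        return n_cg * L / (n_c * n_g)
    if formula == "gc":
        gc = (n_c + n_g) / L
        if gc == 0:
            return 0.0
        return (n_cg / L) / ((gc / 2.0) ** 2)
    raise ValueError(f"unknown CpG formula {formula!r}")


def normalized_cpg_score(
    genome,
    tss: TssSite,
    flank_bp: int = 1500,
    gene_id: str | None = None,
    formula: str = "obs_exp",
) -> PromoterClass:
    """Score the +/-``flank_bp`` promoter window of a TSS and classify HCP/LCP.

    ``genome`` is any mapping of chromosome name to indexable sequence (for
    example a :class:`pyfaidx.Fasta`).  Windows extending past contig bounds
    are truncated with a warning.  Scores strictly above 0.4 are HCP.
    """
    contig = genome[tss.chrom]
    lo = tss.position - flank_bp
    hi = tss.position + flank_bp + 1
    contig_len = len(contig)
    if lo < 0 or hi > contig_len:
        warnings.warn(
            f"promoter window [{lo}, {hi}) of {tss.site_id} truncated to contig bounds",
            stacklevel=2,
        )
        lo, hi = max(lo, 0), min(hi, contig_len)
    seq = str(contig[lo:hi])
    score = cpg_score_from_sequence(seq, formula=formula)
    label = "HCP" if score > HCP_THRESHOLD else "LCP"
    return PromoterClass(gene_id or tss.site_id, score, label)
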