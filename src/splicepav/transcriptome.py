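"""Transcript annotation handling: GTF parsing, TSS grouping, AS-gene detection.

A transcript isoform is represented by its exon chain on a strand.  Two
isoforms of the same gene are considered structurally distinct when their
ordered intron chains differ (for mono-exon transcripts: when their exon
coordinates differ).  A gene is an *alternative-splicing (AS) parent gene*
when it carries at least two structurally distinct isoforms; only isoforms
of AS parent genes enter the downstream presence/absence analysis.

Isoforms of one gene sharing a transcription start site (the strand-aware
5' coordinate) form a *TSS group*, the unit over which relative isoform
abundances (isoform ratios) are computed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from gffutils.feature import feature_from_line


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


class AnnotationConsistencyError(ValueError):
    """Raised when records for one transcript disagree (chrom/strand)."""


@dataclass(frozen=True, order=True)
class ExonInterval:
    """A genomic exon interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"exon coordinates must be positive: {self}")
        if self.start > self.end:
            raise ValueError(f"exon start > end: {self}")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: identifiers, strand and a sorted exon chain."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r} (strandless transcripts have no defined TSS)"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {ex.chrom}, "
                    f"transcript on {self.chrom}"
                )
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"transcript {self.transcript_id}: exons not sorted")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons {a} / {b}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (donor, acceptor) junction pairs; empty for mono-exon."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    def structure_key(self) -> tuple:
        """Splice-structure equivalence key.

        Multi-exon isoforms are identified by their ordered intron chain;
        mono-exon isoforms by their exact exon interval.  Two isoforms with
        identical intron chains but different terminal exon ends map to the
        same key, i.e. they do not count as distinct splice structures.
        """
        if len(self.exons) == 1:
            return ("mono", self.chrom, self.strand, self.exons[0].start, self.exons[0].end)
        return ("chain", self.chrom, self.strand, self.intron_chain())


@dataclass
class GeneModel:
    """A gene locus and its transcript isoforms."""

    gene_id: str
    isoforms: list[TranscriptModel] = field(default_factory=list)

    @property
    def is_as(self) -> bool:
        """True when the gene has >= 2 structurally distinct isoforms."""
        return len({t.structure_key() for t in self.isoforms}) >= 2


@dataclass(frozen=True)
class TssGroup:
    """Isoforms of one gene sharing a transcription start site."""

    gene_id: str
    chrom: str
    strand: str
    tss_position: int
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("TssGroup with no members")

    @property
    def key(self) -> str:
        """Stable identifier used in reports: gene@chrom:pos(strand)."""
        return f"{self.gene_id}@{self.chrom}:{self.tss_position}({self.strand})"


def tss_of(t: TranscriptModel) -> int:
    """Strand-aware 5' coordinate: first exon start on '+', last exon end on '-'."""
    if t.strand == "+":
        return t.exons[0].start
    if t.strand == "-":
        return t.exons[-1].end
    raise ValueError(f"unknown strand {t.strand!r}")  # unreachable after validation


def parse_gtf(path: str | Path | io.TextIOBase) -> list[TranscriptModel]:
    """Read exon records from a GTF file into TranscriptModels.

    Only ``exon`` feature lines are consumed; transcript/gene feature lines
    without exon records contribute nothing (a transcript lacking exons is
    thereby rejected).  Records must carry ``gene_id`` and ``transcript_id``
    attributes.  Coordinates follow the GTF convention (1-based inclusive).

    Raises
    ------
    GtfParseError
        On a malformed line (message includes the line number) or a missing
        required attribute.
    AnnotationConsistencyError
        When exon records for one transcript_id disagree on chrom, strand or
        gene_id.
    ValueError
        For strand symbols other than '+'/'-' (strandless records have no
        defined TSS and are not accepted).
    """
    if isinstance(path, io.TextIOBase):
        lines: Iterable[str] = path
        name = getattr(path, "name", "<stream>")
    else:
        name = str(path)
        lines = Path(path).read_text().splitlines()

    exons: dict[str, list[ExonInterval]] = {}
    info: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if line.count("\t") < 8:
            raise GtfParseError(
                f"{name}: line {lineno}: expected 9 tab-separated columns"
            )
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types
            raise GtfParseError(f"{name}: line {lineno}: {exc}") from exc
        if feat.featuretype != "exon":
            continue
        attrs = feat.attributes
        if "gene_id" not in attrs or "transcript_id" not in attrs:
            raise GtfParseError(
                f"{name}: line {lineno}: exon record lacks gene_id/transcript_id"
            )
        tid = attrs["transcript_id"][0]
        gid = attrs["gene_id"][0]
        if feat.strand not in {"+", "-"}:
            raise ValueError(
                f"{name}: line {lineno}: transcript {tid} has strand "
                f"{feat.strand!r}; a TSS is undefined without strand"
            )
        key = (gid, feat.seqid, feat.strand)
        if tid in info and info[tid] != key:
            raise AnnotationConsistencyError(
                f"{name}: line {lineno}: transcript {tid} previously seen as "
                f"{info[tid]}, now {key}"
            )
        info.setdefault(tid, key)
        exons.setdefault(tid, []).append(
            ExonInterval(feat.seqid, int(feat.start), int(feat.end))
        )

    out = []
    for tid in sorted(exons):
        gid, chrom, strand = info[tid]
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons[tid])),
            )
        )
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "splicepav") -> None:
    """Write exon lines in GTF dialect (gene_id/transcript_id attributes)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.span[0], t.transcript_id)):
            for ex in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{ex.start}\t{ex.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def group_by_gene(transcripts: Iterable[TranscriptModel]) -> dict[str, GeneModel]:
    genes: dict[str, GeneModel] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, GeneModel(t.gene_id)).isoforms.append(t)
    return genes


def gene_of_map(transcripts: Iterable[TranscriptModel]) -> dict[str, str]:
    """transcript_id -> gene_id lookup."""
    return {t.transcript_id: t.gene_id for t in transcripts}


def identify_as_genes(transcripts: Iterable[TranscriptModel]) -> set[str]:
    """Gene ids with at least two structurally unique transcript isoforms.

    Uniqueness means distinct ordered intron chains; for mono-exon isoforms,
    distinct exon intervals (see :meth:`TranscriptModel.structure_key`).
    Genes whose multiple isoform records collapse to one structure are
    excluded: their apparent isoforms are not products of splicing decisions.
    """
    return {gid for gid, g in group_by_gene(transcripts).items() if g.is_as}


def build_tss_groups(
    transcripts: Iterable[TranscriptModel],
    tss_window: int = 0,
) -> list[TssGroup]:
    """Partition each gene's isoforms by shared transcription start site.

    Grouping key is (gene_id, chrom, strand, TSS).  With the default
    ``tss_window=0`` TSS coordinates must match exactly; a positive window
    instead merges, per gene, TSSs within ``tss_window`` bases of a group
    seed (greedy, scanning 5' coordinates in genomic order).  Every isoform
    belongs to exactly one group.
    """
    if tss_window < 0:
        raise ValueError("tss_window must be >= 0")
    groups: list[TssGroup] = []
    by_gene = group_by_gene(list(transcripts))
    for gid in sorted(by_gene):
        members = by_gene[gid].isoforms
        keyed: dict[tuple[str, str, int], list[TranscriptModel]] = {}
        if tss_window == 0:
            for t in members:
                keyed.setdefault((t.chrom, t.strand, tss_of(t)), []).append(t)
        else:
            # greedy window merge within (chrom, strand)
            by_cs: dict[tuple[str, str], list[TranscriptModel]] = {}
            for t in members:
                by_cs.setdefault((t.chrom, t.strand), []).append(t)
            for (chrom, strand), ts in by_cs.items():
                ts = sorted(ts, key=lambda t: (tss_of(t), t.transcript_id))
                seed: int | None = None
                for t in ts:
                    pos = tss_of(t)
                    if seed is None or abs(pos - seed) > tss_window:
                        seed = pos
                    keyed.setdefault((chrom, strand, seed), []).append(t)
        for (chrom, strand, pos) in sorted(keyed):
            ids = tuple(sorted(t.transcript_id for t in keyed[(chrom, strand, pos)]))
            groups.append(TssGroup(gid, chrom, strand, pos, ids))
    return groups
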