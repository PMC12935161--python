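"""Gene/transcript data model, GTF I/O and coordinate transforms.

All in-memory coordinates are 0-based half-open on the genome axis; GTF on
disk uses the standard 1-based inclusive convention, converted only at the
I/O boundary.  Transcript ("spliced") coordinates are 0-based offsets along
the exon chain in 5'->3' orientation, i.e. strand-aware.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field

from .errors import CoordinateError, GtfParseError, ValidationError

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "DisplayMap",
    "parse_gtf",
    "write_gtf",
    "genome_to_transcript",
    "transcript_to_genome",
    "project_interval",
    "tss",
    "build_display_map",
]

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand of a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class FeatureRecord:
    """A non-standard GTF record attached to a transcript (e.g. a projected
    protein domain), preserved verbatim through parse/write round trips."""

    feature_type: str
    interval: GenomicInterval
    attributes: tuple[tuple[str, str], ...] = ()


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] | None = None
    gene_name: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)
    extra_records: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >=1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chrom, strand = self.exons[0].chrom, self.exons[0].strand
        prev_end = -1
        for e in self.exons:
            if e.chrom != chrom or e.strand != strand:
                raise ValidationError(
                    f"{self.transcript_id}: exons span multiple chroms/strands"
                )
            if e.start < prev_end:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
            prev_end = e.end
        if self.cds is not None:
            self.cds = sorted(self.cds, key=lambda c: c.start)
            for c in self.cds:
                if not any(e.contains(c) for e in self.exons):
                    raise ValidationError(
                        f"{self.transcript_id}: CDS {c.start}-{c.end} not inside an exon"
                    )

    # -- derived geometry ------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds) if self.cds else 0

    @property
    def cds_incomplete(self) -> bool:
        """True when the CDS is flagged or its length is not a codon multiple."""
        if self.attributes.get("cds_incomplete", "").lower() == "true":
            return True
        return self.cds is not None and self.cds_length % 3 != 0

    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def cds_transcript_range(self) -> tuple[int, int]:
        """CDS extent in transcript coordinates, (start, end) half-open."""
        if not self.cds:
            raise CoordinateError(f"{self.transcript_id} has no CDS")
        offsets = []
        for c in self.cds:
            g5 = c.start if self.strand == "+" else c.end - 1
            offsets.append(genome_to_transcript(self, g5))
        start = min(offsets)
        return start, start + self.cds_length


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"{self.gene_id}: gene needs >=1 transcript")
        chrom = self.transcripts[0].chrom
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValidationError(
                    f"{self.gene_id}: transcript {t.transcript_id} has gene_id {t.gene_id}"
                )
            if t.chrom != chrom:
                raise ValidationError(f"{self.gene_id}: transcripts on multiple chroms")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def gene_name(self) -> str | None:
        for t in self.transcripts:
            if t.gene_name:
                return t.gene_name
        return None

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged exonic intervals across all isoforms, sorted by start."""
        ivs = sorted((e.start, e.end) for t in self.transcripts for e in t.exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------

def _tx_order_exons(tx: Transcript) -> list[GenomicInterval]:
    """Exons in 5'->3' transcript order."""
    return tx.exons if tx.strand == "+" else list(reversed(tx.exons))


def genome_to_transcript(tx: Transcript, gpos: int) -> int:
    """Map an exonic genomic position to its 0-based spliced-transcript offset."""
    off = 0
    for e in _tx_order_exons(tx):
        if e.start <= gpos < e.end:
            within = gpos - e.start if tx.strand == "+" else e.end - 1 - gpos
            return off + within
        off += len(e)
    raise CoordinateError(
        f"{tx.transcript_id}: position {gpos} is not exonic"
    )


def transcript_to_genome(tx: Transcript, tpos: int) -> int:
    """Inverse of :func:`genome_to_transcript`."""
    if not 0 <= tpos < tx.spliced_length:
        raise CoordinateError(
            f"{tx.transcript_id}: offset {tpos} outside [0, {tx.spliced_length})"
        )
    off = tpos
    for e in _tx_order_exons(tx):
        if off < len(e):
            return e.start + off if tx.strand == "+" else e.end - 1 - off
        off -= len(e)
    raise AssertionError("unreachable")


def project_interval(tx: Transcript, t_start: int, t_end: int) -> list[GenomicInterval]:
    """Project a transcript-space interval [t_start, t_end) to genomic intervals.

    The result is split at exon junctions, covers exactly ``t_end - t_start``
    bases, and is ordered by genomic start.
    """
    if not (0 <= t_start < t_end <= tx.spliced_length):
        raise CoordinateError(
            f"{tx.transcript_id}: invalid transcript range [{t_start}, {t_end})"
        )
    pieces: list[GenomicInterval] = []
    off = 0
    for e in _tx_order_exons(tx):
        lo = max(t_start, off)
        hi = min(t_end, off + len(e))
        if lo < hi:
            if tx.strand == "+":
                gs, ge = e.start + (lo - off), e.start + (hi - off)
            else:
                gs, ge = e.end - (hi - off), e.end - (lo - off)
            pieces.append(GenomicInterval(tx.chrom, gs, ge, tx.strand))
        off += len(e)
    return sorted(pieces, key=lambda p: p.start)


def tss(tx: Transcript) -> int:
    """Genomic coordinate of the transcription start site (5' end)."""
    return tx.exons[0].start if tx.strand == "+" else tx.exons[-1].end - 1


# ---------------------------------------------------------------------------
# display map (intron compression)
# ---------------------------------------------------------------------------

@dataclass
class DisplayMap:
    """Monotone piecewise-linear genomic->display map with compressed introns.

    Exonic segments (taken from the exon union of the locus) map with slope 1;
    each gap between union exons occupies exactly ``intron_display_length``
    display units regardless of its genomic length.
    """

    segments: list[tuple[int, int, float, float]]  # (gstart, gend, dstart, slope)
    intron_display_length: int = 100

    @classmethod
    def from_union(
        cls, union: list[tuple[int, int]], intron_display_length: int = 100
    ) -> "DisplayMap":
        segs: list[tuple[int, int, float, float]] = []
        d = 0.0
        for i, (s, e) in enumerate(union):
            if i > 0:
                ps, pe = union[i - 1][1], s  # the intron gap
                segs.append((ps, pe, d, intron_display_length / (pe - ps)))
                d += intron_display_length
            segs.append((s, e, d, 1.0))
            d += e - s
        return cls(segs, intron_display_length)

    @property
    def genomic_start(self) -> int:
        return self.segments[0][0]

    @property
    def span(self) -> float:
        gs, ge, ds, slope = self.segments[-1]
        return ds + (ge - gs) * slope

    def to_display(self, gpos: int | float) -> float:
        """Display coordinate of a genomic position inside the locus span."""
        gs0 = self.genomic_start
        ge_last = self.segments[-1][1]
        if not gs0 <= gpos <= ge_last:
            raise CoordinateError(f"position {gpos} outside locus [{gs0}, {ge_last}]")
        starts = [s[0] for s in self.segments]
        i = max(0, bisect_right(starts, gpos) - 1)
        gs, ge, ds, slope = self.segments[i]
        return ds + (min(gpos, ge) - gs) * slope

    @property
    def breakpoints(self) -> list[tuple[int, float]]:
        pts = [(gs, ds) for gs, ge, ds, slope in self.segments]
        gs, ge, ds, slope = self.segments[-1]
        pts.append((ge, ds + (ge - gs) * slope))
        return pts


def build_display_map(model: GeneModel, intron_display_length: int = 100) -> DisplayMap:
    """Display map for a locus, computed on the exon union across isoforms.

    Using the union (rather than each isoform's own introns) keeps all lanes
    of a locus on a single shared axis, so TSS guide lines and shared exons
    align vertically across isoforms.
    """
    return DisplayMap.from_union(model.exon_union(), intron_display_length)


# ---------------------------------------------------------------------------
# GTF I/O (GENCODE attribute dialect)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\S+)\s+"((?:[^"\\]|\\.)*)"\s*;')
_STANDARD_FEATURES = {"gene", "transcript", "exon", "CDS"}


def _parse_attrs(text: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(text))
    if not attrs and text.strip():
        raise GtfParseError(f"line {lineno}: cannot parse attribute field {text!r}")
    return attrs


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def parse_gtf(path) -> list[GeneModel]:
    """Parse a GENCODE-dialect GTF into :class:`GeneModel` objects.

    Exon and CDS records are aggregated per transcript_id; transcript-level
    records contribute attributes; any other feature type is preserved as a
    :class:`FeatureRecord` on its transcript so that augmented annotations
    survive a parse -> write round trip.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    extras: dict[str, list[FeatureRecord]] = {}
    tx_attrs: dict[str, dict[str, str]] = {}
    tx_gene: dict[str, str] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            attrs = _parse_attrs(attr_s, lineno)
            if ftype == "gene":
                continue
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id")
            if tid is None or gid is None:
                raise GtfParseError(
                    f"line {lineno}: {ftype} record lacks gene_id/transcript_id"
                )
            if strand not in STRANDS:
                raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if tid not in tx_gene:
                tx_gene[tid] = gid
                order.append(tid)
            if ftype == "exon":
                exons.setdefault(tid, []).append(iv)
            elif ftype == "CDS":
                cds.setdefault(tid, []).append(iv)
            elif ftype == "transcript":
                tx_attrs.setdefault(tid, {}).update(
                    {k: v for k, v in attrs.items()
                     if k not in ("gene_id", "transcript_id")}
                )
            else:
                kept = tuple(
                    (k, v) for k, v in attrs.items()
                    if k not in ("gene_id", "transcript_id")
                )
                extras.setdefault(tid, []).append(FeatureRecord(ftype, iv, kept))

    transcripts: list[Transcript] = []
    for tid in order:
        if tid not in exons:
            raise GtfParseError(f"transcript {tid} has no exon records")
        attrs = tx_attrs.get(tid, {})
        gene_name = attrs.pop("gene_name", None)
        strands = {e.strand for e in exons[tid]} | {c.strand for c in cds.get(tid, [])}
        if len(strands) > 1:
            raise ValidationError(f"transcript {tid}: mixed strands across records")
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=tx_gene[tid],
                exons=exons[tid],
                cds=cds.get(tid),
                gene_name=gene_name,
                attributes=attrs,
                extra_records=extras.get(tid, []),
            )
        )

    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [
        GeneModel(gid, sorted(txs, key=lambda t: t.transcript_id))
        for gid, txs in sorted(by_gene.items())
    ]


def write_gtf(models: list[GeneModel], path) -> None:
    """Write models as GENCODE-dialect GTF with deterministic ordering.

    Records are ordered by (gene_id, transcript_id, genomic start); coordinates
    are converted to the on-disk 1-based inclusive convention.
    """
    def line(chrom, ftype, iv: GenomicInterval, attrs: dict[str, str]) -> str:
        return "\t".join(
            [chrom, "isokit", ftype, str(iv.start + 1), str(iv.end), ".",
             iv.strand, ".", _fmt_attrs(attrs)]
        )

    out: list[str] = ["## isokit gene annotation"]
    for model in sorted(models, key=lambda m: m.gene_id):
        for t in sorted(model.transcripts, key=lambda t: t.transcript_id):
            base = {"gene_id": t.gene_id, "transcript_id": t.transcript_id}
            if t.gene_name:
                base["gene_name"] = t.gene_name
            out.append(line(t.chrom, "transcript", t.span(), {**base, **t.attributes}))
            for e in t.exons:
                out.append(line(t.chrom, "exon", e, base))
            for c in t.cds or []:
                out.append(line(t.chrom, "CDS", c, base))
            for rec in sorted(
                t.extra_records, key=lambda r: (r.feature_type, r.interval.start)
            ):
                out.append(
                    line(t.chrom, rec.feature_type, rec.interval,
                         {**base, **dict(rec.attributes)})
                )
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")
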