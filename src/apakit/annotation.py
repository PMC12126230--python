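"""Strand-aware 3'UTR annotation extraction from transcript models.

Coordinates are 0-based half-open (BED convention) throughout the package.
For each gene the 3'UTR analysed is the region from the CDS 3' boundary of
the transcript carrying the distal-most transcript end, out to that distal
end — the full-length UTR that the breakpoint regression later segments
into short/long isoform territory.  Regions that overlap an exon of a
different gene are flagged ``masked`` because coverage there is ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class ParseError(ValueError):
    """Raised for malformed annotation/coverage input, naming the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval: 0-based half-open [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when >= 1 base is shared (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: its span, exon blocks, and stop-codon-side CDS boundary.

    ``cds_end_3p`` is the genomic coordinate of the CDS boundary nearest the
    3' end of the transcript: thickEnd on '+', thickStart on '-'.
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    cds_end_3p: int
    exon_blocks: tuple[GenomicInterval, ...]

    def __post_init__(self):
        prev_end = None
        for ex in self.exon_blocks:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"{self.transcript_id}: exon {ex.start}-{ex.end} outside "
                    f"transcript span"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exon blocks overlap or unsorted"
                )
            prev_end = ex.end
        if not (self.interval.start <= self.cds_end_3p <= self.interval.end):
            raise ValueError(
                f"{self.transcript_id}: cds_end_3p {self.cds_end_3p} outside "
                f"transcript span"
            )


@dataclass(frozen=True)
class UTRRegion:
    """The per-gene 3'UTR interval with its annotated distal end.

    ``distal_end`` equals region.end on '+' and region.start on '-'; it is
    the genomic coordinate of the annotated distal poly(A) site.
    """

    gene_id: str
    region: GenomicInterval
    distal_end: int
    source_transcripts: tuple[str, ...]
    masked: bool = False

    def __post_init__(self):
        expect = self.region.end if self.region.strand == "+" else self.region.start
        if self.distal_end != expect:
            raise ValueError(
                f"{self.gene_id}: distal_end {self.distal_end} inconsistent "
                f"with strand {self.region.strand}"
            )

    def __len__(self) -> int:
        return len(self.region)


def _split_name(name: str) -> tuple[str, str]:
    """BED name -> (gene_id, transcript_id). 'GENE|TX' style supported."""
    if "|" in name:
        first, second, *_ = name.split("|")
        return first, second
    return name, name


def read_gene_models(path) -> list[TranscriptModel]:
    """Read transcript models from a BED12 file.

    Tab- or space-separated; trailing commas in blockSizes/blockStarts are
    tolerated; ``track``/``browser``/``#`` lines are skipped.  thickStart /
    thickEnd give the CDS span; the stop-codon-side boundary is thickEnd on
    '+' and thickStart on '-'.

    Raises
    ------
    ParseError
        On any malformed line, naming its 1-based line number.
    """
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 BED fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if len(sizes) != block_count or len(offsets) != block_count:
                raise ParseError(
                    f"{path}: line {lineno}: blockSizes/blockStarts "
                    f"inconsistent with blockCount={block_count}"
                )
            try:
                interval = GenomicInterval(chrom, start, end, strand)
                exons = tuple(
                    GenomicInterval(chrom, start + off, start + off + size, strand)
                    for off, size in zip(offsets, sizes)
                )
                gene_id, tx_id = _split_name(name)
                cds_end_3p = thick_end if strand == "+" else thick_start
                models.append(
                    TranscriptModel(tx_id, gene_id, interval, cds_end_3p, exons)
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return models


def read_gtf_models(path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file (feature types exon and CDS).

    GTF 1-based closed coordinates are converted to 0-based half-open at
    this boundary.  Transcripts lacking a CDS record are skipped (no 3'UTR
    can be defined for them).
    """
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    cds: dict[tuple[str, str], list[GenomicInterval]] = {}
    meta: dict[tuple[str, str], tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GTF fields")
            chrom, _, feature, start1, end1, _, strand, _, attrs = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            attr = {}
            for part in attrs.rstrip(";").split(";"):
                part = part.strip()
                if not part:
                    continue
                key, _, val = part.partition(" ")
                attr[key] = val.strip().strip('"')
            try:
                tx = attr["transcript_id"]
                gene = attr.get("gene_id", tx)
            except KeyError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: missing transcript_id"
                ) from exc
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            key = (chrom, tx)
            meta[key] = (gene, strand)
            (exons if feature == "exon" else cds).setdefault(key, []).append(iv)

    models = []
    for key, exon_list in exons.items():
        if key not in cds:
            continue
        gene, strand = meta[key]
        exon_list = sorted(exon_list, key=lambda iv: iv.start)
        chrom, tx = key
        span = GenomicInterval(chrom, exon_list[0].start, exon_list[-1].end, strand)
        cds_list = cds[key]
        cds_end_3p = (
            max(iv.end for iv in cds_list)
            if strand == "+"
            else min(iv.start for iv in cds_list)
        )
        models.append(TranscriptModel(tx, gene, span, cds_end_3p, tuple(exon_list)))
    return models


def extract_3utrs(
    models: list[TranscriptModel], min_utr_length: int = 150
) -> list[UTRRegion]:
    """Derive one 3'UTR region per gene from its transcript models.

    Per gene: the transcript with the distal-most transcript end (max end on
    '+', min start on '-') defines both the distal end and the CDS 3'
    boundary; the UTR spans between them.  Regions shorter than
    ``min_utr_length`` are skipped (a breakpoint search window must remain
    after margins).  Regions overlapping any exon of a *different* gene are
    flagged masked — intronic overlap does not confound exonic coverage and
    is ignored.

    Output is sorted by gene_id, so it is invariant to input order.
    """
    if not models:
        raise ValueError("no transcript models supplied")

    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    regions: list[UTRRegion] = []
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        chroms = {(t.interval.chrom, t.interval.strand) for t in txs}
        if len(chroms) > 1:
            logger.warning(
                "gene %s: transcripts on multiple chromosomes/strands; skipped",
                gene_id,
            )
            continue
        strand = txs[0].interval.strand
        if strand == "+":
            distal_tx = max(txs, key=lambda t: (t.interval.end, t.transcript_id))
            start, end = distal_tx.cds_end_3p, distal_tx.interval.end
            distal = end
        else:
            distal_tx = min(txs, key=lambda t: (t.interval.start, t.transcript_id))
            start, end = distal_tx.interval.start, distal_tx.cds_end_3p
            distal = start
        if end - start < min_utr_length:
            logger.info(
                "gene %s: 3'UTR length %d < min_utr_length %d; skipped",
                gene_id, end - start, min_utr_length,
            )
            continue
        region = GenomicInterval(txs[0].interval.chrom, start, end, strand)
        sources = tuple(sorted(t.transcript_id for t in txs))
        regions.append(UTRRegion(gene_id, region, distal, sources))

    # mask regions overlapping exons of other genes
    masked_out: list[UTRRegion] = []
    for reg in regions:
        masked = any(
            m.gene_id != reg.gene_id and reg.region.overlaps(ex)
            for m in models
            for ex in m.exon_blocks
        )
        masked_out.append(
            UTRRegion(reg.gene_id, reg.region, reg.distal_end,
                      reg.source_transcripts, masked)
            if masked else reg
        )
    return masked_out


def write_utr_table(regions: list[UTRRegion], path) -> None:
    """Write UTR regions as BED6 + gene_id, source_transcripts, masked."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\t"
            "gene_id\tsource_transcripts\tmasked\n"
        )
        for r in regions:
            fh.write(
                f"{r.region.chrom}\t{r.region.start}\t{r.region.end}\t"
                f"{r.gene_id}\t0\t{r.region.strand}\t{r.gene_id}\t"
                f"{','.join(r.source_transcripts)}\t{int(r.masked)}\n"
            )


def read_utr_table(path) -> list[UTRRegion]:
    """Read back a UTR table written by :func:`write_utr_table`."""
    regions = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5])
            distal = iv.end if f[5] == "+" else iv.start
            regions.append(
                UTRRegion(f[6], iv, distal, tuple(f[7].split(",")), bool(int(f[8])))
            )
    return regions
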