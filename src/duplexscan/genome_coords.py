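"""Projection of transcript-space alignments to the genome and classification.

Interactions are classified two ways: by the mRNA region they cover on the
target (CDS, 5' UTR, 3' UTR, CDS-and-UTR, or non-coding for non-coding
biotypes) and by genomic locality — *cis* for gene pairs that occupy
overlapping genomic loci on opposite strands (natural antisense
configuration), *trans* for everything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .duplex_align import DuplexAlignment
from .formats_io import GenomicInterval
from .premrna import PremrnaMap, TranscriptModel

REGION_CLASSES = ("CDS", "UTR5", "UTR3", "CDS_UTR", "noncoding")


@dataclass(frozen=True)
class InteractionRecord:
    """A genome-projected interaction with region class and locality."""

    alignment: DuplexAlignment
    lnc_genomic: Tuple[GenomicInterval, ...]
    target_genomic: Tuple[GenomicInterval, ...]
    region_class: str
    locality: str

    @property
    def interaction_id(self) -> str:
        a = self.alignment
        return (
            f"{a.lnc_id}|{a.target_id}|{a.lnc_interval[0]}-{a.lnc_interval[1]}|"
            f"{a.target_interval[0]}-{a.target_interval[1]}"
        )


def project_to_genome(
    interval: Tuple[int, int], model: TranscriptModel
) -> List[GenomicInterval]:
    """Split a mature-transcript interval into genomic exon blocks.

    Blocks come back in genomic order; minus-strand transcripts map their
    5'->3' axis onto descending genomic coordinates.
    """
    start, end = interval
    if not (0 <= start < end <= model.exonic_length):
        raise ValueError(
            f"interval {interval} exceeds transcript length {model.exonic_length}"
        )
    blocks: List[GenomicInterval] = []
    offset = 0
    for exon in model._exons_transcript_order():
        lo = max(start, offset)
        hi = min(end, offset + len(exon))
        if lo < hi:
            if model.strand == "+":
                g0 = exon.start + (lo - offset)
                g1 = exon.start + (hi - offset)
            else:
                g1 = exon.end - (lo - offset)
                g0 = exon.end - (hi - offset)
            blocks.append(
                GenomicInterval(model.chrom, g0, g1, model.strand, model.transcript_id)
            )
        offset += len(exon)
    blocks.sort(key=lambda b: b.start)
    return blocks


def project_to_transcript(
    blocks: Sequence[GenomicInterval], model: TranscriptModel
) -> Tuple[int, int]:
    """Map genomic exon blocks back to one mature-transcript interval."""
    positions = []
    for b in blocks:
        positions.append(model.genomic_to_transcript(b.start))
        positions.append(model.genomic_to_transcript(b.end - 1))
    return min(positions), max(positions) + 1


def merge_regions(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Minimal sorted union of intervals, merged per (chrom, strand); idempotent."""
    groups: Dict[Tuple[str, str], List[GenomicInterval]] = {}
    for iv in intervals:
        groups.setdefault((iv.chrom, iv.strand), []).append(iv)
    merged: List[GenomicInterval] = []
    for (chrom, strand), ivs in groups.items():
        ivs.sort(key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e, strand))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e, strand))
    merged.sort(key=lambda v: (v.chrom, v.start, v.end, v.strand))
    return merged


def _mature_pieces_for_alignment(
    alignment: DuplexAlignment, model: TranscriptModel
) -> List[Tuple[int, int]]:
    """Mature-transcript sub-intervals covered by the alignment's target span.

    In mRNA mode this is the target interval itself; in pre-mRNA mode the
    genomic footprint is intersected with the exons and mapped to mature
    coordinates (possibly several pieces, possibly none for intron-only hits).
    """
    if alignment.mode == "mRNA":
        return [alignment.target_interval]
    pmap = PremrnaMap(model.chrom, model.strand, *model.span)
    g0, g1 = pmap.interval_to_genomic(*alignment.target_interval)
    pieces = []
    for exon in model.exons:
        a, b = max(g0, exon.start), min(g1, exon.end)
        if a < b:
            ta = model.genomic_to_transcript(a)
            tb = model.genomic_to_transcript(b - 1)
            pieces.append((min(ta, tb), max(ta, tb) + 1))
    return sorted(pieces)


def classify_region(alignment: DuplexAlignment, model: TranscriptModel) -> str:
    """Region of the mature target covered by the interaction.

    Non-coding biotypes are always 'noncoding'. For coding targets the class
    is decided by which of 5' UTR / CDS / 3' UTR the covered mature pieces
    overlap: CDS plus any UTR gives CDS_UTR; both UTRs without CDS (possible
    only for intron-containing spans) goes to the larger UTR overlap; a
    pre-mRNA hit with no exonic overlap is classified by where its intron
    sits within the mature transcript.
    """
    if model.biotype != "protein_coding":
        return "noncoding"
    if model.cds is None:
        raise ValueError(f"{model.transcript_id}: protein_coding model lacks CDS")
    cds_s, cds_e = model.cds_transcript_interval()
    length = model.exonic_length
    pieces = _mature_pieces_for_alignment(alignment, model)
    if not pieces:
        # intron-only pre-mRNA hit: classify by the junction's mature position
        pmap = PremrnaMap(model.chrom, model.strand, *model.span)
        g0, g1 = pmap.interval_to_genomic(*alignment.target_interval)
        # mature position where the enclosing intron is spliced out
        if model.strand == "+":
            cut = sum(len(e) for e in model.exons if e.end <= g0)
        else:
            cut = sum(len(e) for e in model.exons if e.start >= g1)
        if cut <= cds_s:
            return "UTR5"
        if cut >= cds_e:
            return "UTR3"
        return "CDS"
    o5 = sum(max(0, min(e, cds_s) - max(s, 0)) for s, e in pieces)
    oc = sum(max(0, min(e, cds_e) - max(s, cds_s)) for s, e in pieces)
    o3 = sum(max(0, min(e, length) - max(s, cds_e)) for s, e in pieces)
    if oc > 0 and (o5 > 0 or o3 > 0):
        return "CDS_UTR"
    if oc > 0:
        return "CDS"
    if o5 > 0 and o3 > 0:
        return "UTR3" if o3 >= o5 else "UTR5"
    if o5 > 0:
        return "UTR5"
    return "UTR3"


def classify_cis_trans(
    gene_span_a: GenomicInterval, gene_span_b: GenomicInterval
) -> str:
    """cis iff same chromosome, >=1 bp span overlap and opposite strands."""
    if (
        gene_span_a.chrom == gene_span_b.chrom
        and gene_span_a.strand != gene_span_b.strand
        and gene_span_a.overlap(gene_span_b) >= 1
    ):
        return "cis"
    return "trans"


def gene_span(models: Sequence[TranscriptModel]) -> GenomicInterval:
    """Union of a gene's transcripts' exonic extents."""
    if not models:
        raise ValueError("no transcript models for gene")
    chrom = models[0].chrom
    strand = models[0].strand
    start = min(m.span[0] for m in models)
    end = max(m.span[1] for m in models)
    return GenomicInterval(chrom, start, end, strand, models[0].gene_id)


def build_interaction(
    alignment: DuplexAlignment,
    lnc_model: TranscriptModel,
    target_model: TranscriptModel,
    lnc_gene_span: Optional[GenomicInterval] = None,
    target_gene_span: Optional[GenomicInterval] = None,
) -> InteractionRecord:
    """Project both molecules to the genome and attach class and locality."""
    lnc_blocks = tuple(project_to_genome(alignment.lnc_interval, lnc_model))
    if alignment.mode == "pre-mRNA":
        pmap = PremrnaMap(target_model.chrom, target_model.strand, *target_model.span)
        g0, g1 = pmap.interval_to_genomic(*alignment.target_interval)
        target_blocks = (
            GenomicInterval(
                target_model.chrom, g0, g1, target_model.strand,
                target_model.transcript_id,
            ),
        )
    else:
        target_blocks = tuple(project_to_genome(alignment.target_interval, target_model))
    return InteractionRecord(
        alignment=alignment,
        lnc_genomic=lnc_blocks,
        target_genomic=target_blocks,
        region_class=classify_region(alignment, target_model),
        locality=classify_cis_trans(
            lnc_gene_span or lnc_model.gene_span_interval(),
            target_gene_span or target_model.gene_span_interval(),
        ),
    )
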