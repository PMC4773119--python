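"""Transcript models, pre-mRNA query construction and junction logic.

A pre-mRNA query is the unspliced transcript (5'->3' on the transcript's own
strand) in which the interior of every long intron is masked with N: only the
``flank`` nucleotides (250 by default) nearest each splice site are kept
searchable, because that is where splice-signal-masking interactions act.
Masking replaces bases rather than deleting them, so pre-mRNA coordinates map
linearly and invertibly onto the genome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .formats_io import GenomicInterval, PathLike, SequenceRecord, _open_text, revcomp


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure, strand, CDS span and biotype of one transcript.

    ``exons`` are genomic intervals sorted by genomic start and non-overlapping;
    ``cds`` is the genomic (start, end) span of the coding region, or None for
    non-coding biotypes.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[GenomicInterval, ...]
    cds: Optional[Tuple[int, int]] = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
        if self.cds is not None:
            s, e = self.cds
            if not (self.span[0] <= s < e <= self.span[1]):
                raise ValueError(f"{self.transcript_id}: CDS outside exon span")

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def premrna_length(self) -> int:
        s, e = self.span
        return e - s

    def gene_span_interval(self) -> GenomicInterval:
        s, e = self.span
        return GenomicInterval(self.chrom, s, e, self.strand, self.gene_id)

    # ---- mature-transcript coordinate machinery ----

    def _exons_transcript_order(self) -> List[GenomicInterval]:
        return list(self.exons) if self.strand == "+" else list(self.exons)[::-1]

    def genomic_to_transcript(self, g: int) -> int:
        """Map an exonic genomic position to mature-transcript coordinates."""
        offset = 0
        for exon in self._exons_transcript_order():
            if exon.start <= g < exon.end:
                if self.strand == "+":
                    return offset + (g - exon.start)
                return offset + (exon.end - 1 - g)
            offset += len(exon)
        raise ValueError(f"{self.transcript_id}: genomic position {g} not exonic")

    def transcript_to_genomic(self, p: int) -> int:
        if not (0 <= p < self.exonic_length):
            raise ValueError(f"{self.transcript_id}: transcript position {p} out of range")
        offset = 0
        for exon in self._exons_transcript_order():
            if p < offset + len(exon):
                if self.strand == "+":
                    return exon.start + (p - offset)
                return exon.end - 1 - (p - offset)
            offset += len(exon)
        raise AssertionError("unreachable")

    def cds_transcript_interval(self) -> Tuple[int, int]:
        """The CDS as a half-open interval in mature-transcript coordinates."""
        if self.cds is None:
            raise ValueError(f"{self.transcript_id}: no CDS")
        s, e = self.cds
        a = self.genomic_to_transcript(s if self.strand == "+" else e - 1)
        b = self.genomic_to_transcript(e - 1 if self.strand == "+" else s)
        return a, b + 1

    def mature_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = self._chrom_seq(genome)
        parts = [chrom_seq[e.start : e.end] for e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    def _chrom_seq(self, genome: Mapping[str, str]) -> str:
        if self.chrom not in genome:
            raise KeyError(f"chromosome {self.chrom!r} absent from genome")
        chrom_seq = genome[self.chrom]
        if self.span[1] > len(chrom_seq):
            raise ValueError(
                f"{self.transcript_id}: exon beyond end of {self.chrom}"
            )
        return chrom_seq

    # ---- splice junctions ----

    def internal_boundaries(self) -> List[int]:
        """Genomic positions of internal exon boundaries (splice sites)."""
        cuts = []
        for k, exon in enumerate(self.exons):
            if k > 0:
                cuts.append(exon.start)
            if k < len(self.exons) - 1:
                cuts.append(exon.end)
        return cuts

    def junction_cuts_premrna(self) -> List[int]:
        """Splice-site cut points in pre-mRNA coordinates, sorted ascending."""
        s, e = self.span
        if self.strand == "+":
            cuts = [b - s for b in self.internal_boundaries()]
        else:
            cuts = [e - b for b in self.internal_boundaries()]
        return sorted(cuts)


@dataclass(frozen=True)
class PremrnaMap:
    """Invertible linear map between pre-mRNA and genomic coordinates."""

    chrom: str
    strand: str
    span_start: int
    span_end: int

    def to_genomic(self, p: int) -> int:
        if not (0 <= p < self.span_end - self.span_start):
            raise ValueError(f"pre-mRNA position {p} out of range")
        if self.strand == "+":
            return self.span_start + p
        return self.span_end - 1 - p

    def to_premrna(self, g: int) -> int:
        if not (self.span_start <= g < self.span_end):
            raise ValueError(f"genomic position {g} outside pre-mRNA span")
        if self.strand == "+":
            return g - self.span_start
        return self.span_end - 1 - g

    def interval_to_genomic(self, start: int, end: int) -> Tuple[int, int]:
        """Map a half-open pre-mRNA interval to its genomic half-open interval."""
        if start >= end:
            raise ValueError("empty interval")
        a = self.to_genomic(start)
        b = self.to_genomic(end - 1)
        return (a, b + 1) if self.strand == "+" else (b, a + 1)


def build_premrna_query(
    model: TranscriptModel,
    genome: Mapping[str, str],
    flank: int = 250,
) -> Tuple[SequenceRecord, PremrnaMap]:
    """Unspliced transcript with deep intron interiors masked to N.

    For every intron longer than 2*flank, positions more than ``flank`` bases
    from both flanking splice sites are replaced by N; shorter introns are
    kept entire. Returns the masked sequence (transcript orientation) and the
    coordinate map.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    chrom_seq = model._chrom_seq(genome)
    s, e = model.span
    seq = list(chrom_seq[s:e])
    for left, right in zip(model.exons, model.exons[1:]):
        intron_len = right.start - left.end
        if intron_len > 2 * flank:
            for g in range(left.end + flank, right.start - flank):
                seq[g - s] = "N"
    out = "".join(seq)
    if model.strand == "-":
        out = revcomp(out)
    return (
        SequenceRecord(model.transcript_id, out),
        PremrnaMap(model.chrom, model.strand, s, e),
    )


def spans_junction(alignment, model: TranscriptModel) -> bool:
    """True iff the target interval strictly contains a splice junction.

    The junction must be interior to the alignment's target interval (at
    least one paired base on each side); an alignment ending exactly at the
    boundary does not span it.
    """
    if alignment.mode != "pre-mRNA":
        raise ValueError("spans_junction requires a pre-mRNA mode alignment")
    start, end = alignment.target_interval
    if end > model.premrna_length:
        raise ValueError(
            f"target interval {alignment.target_interval} exceeds pre-mRNA length"
        )
    return any(start < c < end for c in model.junction_cuts_premrna())


# ---------------------------------------------------------------------------
# GTF-like annotation dialect: tab-delimited exon/CDS records with 1-based
# inclusive coordinates and gene_id/transcript_id/biotype attributes.
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: PathLike) -> List[TranscriptModel]:
    """Parse the GTF-like annotation into transcript models."""
    exons: Dict[str, List[Tuple[str, str, int, int]]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Dict[str, str]] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-delimited fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            try:
                tid = attr["transcript_id"]
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: missing transcript_id") from exc
            gstart, gend = int(start) - 1, int(end)  # to 0-based half-open
            meta.setdefault(
                tid,
                {
                    "gene_id": attr.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attr.get(
                        "transcript_biotype", attr.get("biotype", "protein_coding")
                    ),
                },
            )
            if feature == "exon":
                exons.setdefault(tid, []).append((chrom, strand, gstart, gend))
            else:
                cds.setdefault(tid, []).append((gstart, gend))
    models = []
    for tid, ex in exons.items():
        info = meta[tid]
        ivs = tuple(
            GenomicInterval(info["chrom"], s, e, info["strand"], tid)
            for _, _, s, e in sorted(ex, key=lambda x: x[2])
        )
        cds_span = None
        if tid in cds:
            cds_span = (min(s for s, _ in cds[tid]), max(e for _, e in cds[tid]))
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=ivs,
                cds=cds_span,
                biotype=info["biotype"],
            )
        )
    models.sort(key=lambda m: (m.chrom, m.span[0], m.transcript_id))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'transcript_biotype "{m.biotype}";'
            )
            for exon in m.exons:
                out.write(
                    f"{m.chrom}\tduplexscan\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
            if m.cds is not None:
                s, e = m.cds
                for exon in m.exons:
                    a, b = max(exon.start, s), min(exon.end, e)
                    if a < b:
                        out.write(
                            f"{m.chrom}\tduplexscan\tCDS\t{a + 1}\t{b}\t.\t"
                            f"{m.strand}\t.\t{attrs}\n"
                        )
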