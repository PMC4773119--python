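"""Rule filters that nominate interactions for regulatory mechanisms.

Four mechanisms are screened, each by a geometric rule on genomic features:

* splice-signal masking — a splicing-factor CLIP site lies entirely within a
  junction-spanning pre-mRNA interaction region, on the same strand; the
  spanned splice sites are classified alternative vs constitutive.
* miRNA-site masking — at least half of a (CLIP-supported, merged) miRNA
  target site lies within an mRNA-mode interaction region.
* Staufen-mediated decay — an Alu element lies entirely within the
  interaction region and entirely within the 3' UTR of a coding target.
* editing-site overlap — a single-base A-to-I editing position falls inside
  the interaction region.

Containment is tested against the union of the interaction's genomic
fragments. All rules are strand-aware: the feature must sit on the target
transcript's strand (stated in the source protocol for the splice filter;
applied throughout because strand-blind matching would admit spurious
antisense hits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .formats_io import GenomicInterval
from .genome_coords import InteractionRecord, merge_regions, project_to_genome
from .premrna import TranscriptModel


@dataclass(frozen=True)
class RegulatoryAnnotation:
    """One interaction x evidence-feature match for one mechanism."""

    interaction: InteractionRecord
    mechanism: str  # splice_mask | mirna_mask | smd | editing
    evidence: Tuple[GenomicInterval, ...]
    splice_site_class: Optional[str] = None  # alternative | constitutive

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("annotation requires non-empty evidence")


def _merged_region(interaction: InteractionRecord) -> List[GenomicInterval]:
    return merge_regions(interaction.target_genomic)


def _contained(feature: GenomicInterval, fragments: Sequence[GenomicInterval]) -> bool:
    return any(frag.contains(feature) for frag in fragments)


def _overlap_with(feature: GenomicInterval, fragments: Sequence[GenomicInterval]) -> int:
    return sum(frag.overlap(feature) for frag in fragments)


def _target_strand(interaction: InteractionRecord) -> str:
    return interaction.target_genomic[0].strand


def _models_by_transcript(
    models: Iterable[TranscriptModel],
) -> Dict[str, TranscriptModel]:
    return {m.transcript_id: m for m in models}


def _models_by_gene(
    models: Iterable[TranscriptModel],
) -> Dict[str, List[TranscriptModel]]:
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    return by_gene


def classify_splice_site(
    position: int, gene_models: Sequence[TranscriptModel]
) -> str:
    """'constitutive' iff every covering isoform uses the boundary.

    ``position`` is a genomic exon boundary (an exon start or end, in the
    half-open convention) of at least one transcript of the gene; an isoform
    "covers" the position when its genomic span contains it.
    """
    users = [m for m in gene_models if position in m.internal_boundaries()]
    if not users:
        raise ValueError(f"position {position} is not an exon boundary of any isoform")
    covering = [
        m for m in gene_models if m.span[0] <= position <= m.span[1]
    ]
    return (
        "constitutive"
        if all(position in m.internal_boundaries() for m in covering)
        else "alternative"
    )


def splice_mask_candidates(
    interactions: Sequence[InteractionRecord],
    clip_sites: Sequence[GenomicInterval],
    models: Iterable[TranscriptModel],
) -> List[RegulatoryAnnotation]:
    """Splice-signal masking: CLIP site entirely within the region, same strand.

    ``interactions`` should already be the junction-spanning pre-mRNA set.
    Each kept (interaction, CLIP site) pair is annotated with the class of the
    spanned splice sites: 'alternative' if any spanned site is alternative.
    """
    for site in clip_sites:
        if site.strand not in ("+", "-"):
            raise ValueError("CLIP sites must carry a strand")
    by_tid = _models_by_transcript(models)
    by_gene = _models_by_gene(by_tid.values())
    out: List[RegulatoryAnnotation] = []
    for inter in interactions:
        fragments = _merged_region(inter)
        strand = _target_strand(inter)
        model = by_tid[inter.alignment.target_id]
        gene_models = by_gene[model.gene_id]
        g0 = min(f.start for f in fragments)
        g1 = max(f.end for f in fragments)
        spanned = [
            b for b in model.internal_boundaries() if g0 < b < g1
        ]
        site_class = None
        if spanned:
            classes = {classify_splice_site(b, gene_models) for b in spanned}
            site_class = "alternative" if "alternative" in classes else "constitutive"
        for site in clip_sites:
            if site.strand != strand:
                continue
            if _contained(site, fragments):
                out.append(
                    RegulatoryAnnotation(
                        interaction=inter,
                        mechanism="splice_mask",
                        evidence=(site,),
                        splice_site_class=site_class,
                    )
                )
    return out


def intersect_site_sets(
    clip_sites: Sequence[GenomicInterval],
    predicted_sites: Sequence[GenomicInterval],
) -> List[GenomicInterval]:
    """Per-strand intersection of the two merged site sets."""
    merged_clip = merge_regions(clip_sites)
    merged_pred = merge_regions(predicted_sites)
    out: List[GenomicInterval] = []
    for c in merged_clip:
        for p in merged_pred:
            if c.chrom != p.chrom or c.strand != p.strand:
                continue
            s, e = max(c.start, p.start), min(c.end, p.end)
            if s < e:
                out.append(GenomicInterval(c.chrom, s, e, c.strand))
    out.sort(key=lambda v: (v.chrom, v.start, v.end, v.strand))
    return out


def mirna_mask_candidates(
    interactions: Sequence[InteractionRecord],
    mirna_sites: Sequence[GenomicInterval],
) -> List[RegulatoryAnnotation]:
    """miRNA-site masking: >= half of the site within the interaction region.

    ``mirna_sites`` is the pre-intersected CLIP-supported merged set. With an
    odd site length, "half" rounds up (ceil)."""
    out: List[RegulatoryAnnotation] = []
    for site in mirna_sites:
        if len(site) == 0:
            raise ValueError("zero-length miRNA site")
    for inter in interactions:
        fragments = _merged_region(inter)
        strand = _target_strand(inter)
        for site in mirna_sites:
            if site.strand != strand:
                continue
            if _overlap_with(site, fragments) >= math.ceil(len(site) / 2):
                out.append(
                    RegulatoryAnnotation(
                        interaction=inter, mechanism="mirna_mask", evidence=(site,)
                    )
                )
    return out


def smd_candidates(
    interactions: Sequence[InteractionRecord],
    alu_elements: Sequence[GenomicInterval],
    models: Iterable[TranscriptModel],
) -> List[RegulatoryAnnotation]:
    """Staufen-mediated-decay: Alu within the region AND within a coding 3' UTR."""
    by_tid = _models_by_transcript(models)
    out: List[RegulatoryAnnotation] = []
    for inter in interactions:
        model = by_tid[inter.alignment.target_id]
        if model.biotype != "protein_coding" or model.cds is None:
            continue
        _, cds_e = model.cds_transcript_interval()
        if cds_e >= model.exonic_length:
            continue  # no 3' UTR
        utr3_blocks = project_to_genome((cds_e, model.exonic_length), model)
        fragments = _merged_region(inter)
        strand = _target_strand(inter)
        for alu in alu_elements:
            if alu.strand != strand:
                continue
            if _contained(alu, fragments) and _contained(alu, utr3_blocks):
                out.append(
                    RegulatoryAnnotation(
                        interaction=inter, mechanism="smd", evidence=(alu,)
                    )
                )
    return out


def editing_candidates(
    interactions: Sequence[InteractionRecord],
    editing_sites: Sequence[GenomicInterval],
) -> List[RegulatoryAnnotation]:
    """A-to-I editing: a single-base site inside the interaction region."""
    for site in editing_sites:
        if len(site) != 1:
            raise ValueError(
                f"editing site {site.chrom}:{site.start}-{site.end} is not single-base"
            )
    out: List[RegulatoryAnnotation] = []
    for inter in interactions:
        fragments = _merged_region(inter)
        strand = _target_strand(inter)
        for site in editing_sites:
            if site.strand != strand:
                continue
            if _contained(site, fragments):
                out.append(
                    RegulatoryAnnotation(
                        interaction=inter, mechanism="editing", evidence=(site,)
                    )
                )
    return out
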