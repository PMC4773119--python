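"""Synthetic fixture generator with a machine-readable truth table.

The generator builds a miniature but complete study system: a genome of
eleven small chromosomes, twenty three-exon genes (alternating strands, one
gene with a skipped-exon isoform, four non-coding genes), ten lncRNAs — nine
intergenic and one natural antisense transcript sitting inside the first
gene's long intron — plus planted lncRNA:target duplexes, regulatory feature
BEDs and per-library read-mapping summaries.

Planted duplexes are perfect Watson-Crick complements with controlled
G:C / A:T composition, so their score is a closed form (4*n_gc + 2*n_at) and
their coordinates are known exactly. Each plant is flanked by short poly-A
guard runs on both molecules: under the pairing matrix an A:A face has no
positive column, so the optimal local alignment provably coincides with the
planted segment and cannot extend by chance into the flanks. The antisense
lncRNA yields two deterministic cis pre-mRNA hits whose boundaries are set
by the intron-masking window on one side and the lncRNA ends on the other.

Every feature of the regulatory BEDs is placed either in rule-satisfying or
rule-violating geometry on purpose; truth counts come from that construction,
not from running the filters. ``perturbation`` moves exactly one
rule-satisfying feature into violating geometry, changing exactly one truth
count by one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .formats_io import (
    GenomicInterval,
    SequenceRecord,
    revcomp,
    write_bed,
    write_fasta,
)
from .premrna import TranscriptModel, write_gtf

# ---- structural constants of the miniature gene model ----
EXON_LENS = (200, 200, 400)
INTRON_LENS = (600, 500)
GENE_SPAN = 1900
CDS_T = (80, 450)  # mature-transcript coordinates
CHROM_LEN = 4300
GENE_OFFSETS = (100, 2200)
LNC_LEN = 600
LNC_CHROM = "chrL"
LNC_CHROM_LEN = 8000
GUARD = 8

# exon spans relative to the gene offset, genomic order
_EXON_G = ((0, 200), (800, 1000), (1500, 1900))
_INTRON_G = ((200, 800), (1000, 1500))

PERTURBATIONS = (
    "alu_outside_utr3",
    "mirna_below_half",
    "clip_partial",
    "editing_at_end",
)


@dataclass(frozen=True)
class PlantSpec:
    """One planted duplex: a perfect complement inserted into a lncRNA."""

    name: str
    lnc_id: str
    target_id: str
    lnc_offset: int
    kind: str  # 'mature' | 'premrna'
    start: int  # on the target, in `kind` coordinates
    length: int
    n_gc: int
    region_class: str = "CDS"

    @property
    def score(self) -> int:
        return 4 * self.n_gc + 2 * (self.length - self.n_gc)


def default_plants() -> Tuple[PlantSpec, ...]:
    return (
        PlantSpec("P1", "LNC00", "T02", 50, "mature", 460, 120, 80, "UTR3"),
        PlantSpec("P2", "LNC01", "T04", 50, "mature", 250, 60, 40, "CDS"),
        PlantSpec("P3", "LNC02", "T05", 200, "mature", 430, 40, 27, "CDS_UTR"),
        PlantSpec("P4", "LNC03", "T06", 300, "premrna", 170, 60, 24, "CDS"),
        PlantSpec("P5", "LNC04", "T16", 400, "mature", 100, 60, 40, "noncoding"),
    )


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic fixture."""

    n_genes: int = 20
    n_lnc: int = 10
    flank: int = 250
    threshold_mrna: int = 107
    threshold_premrna: int = 108
    plants: Tuple[PlantSpec, ...] = field(default_factory=default_plants)
    perturbation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.perturbation is not None and self.perturbation not in PERTURBATIONS:
            raise ValueError(f"unknown perturbation {self.perturbation!r}")


@dataclass
class Fixture:
    """In-memory fixture bundle plus (optionally) the on-disk paths."""

    config: FixtureConfig
    seed: int
    genome: Dict[str, str]
    models: List[TranscriptModel]
    lnc_records: List[SequenceRecord]
    target_records: List[SequenceRecord]
    clip_sites: List[GenomicInterval]
    mirna_clip: List[GenomicInterval]
    mirna_predicted: List[GenomicInterval]
    alu_elements: List[GenomicInterval]
    editing_sites: List[GenomicInterval]
    mapping_rows: List[Tuple[str, str, str, int]]
    gene_map: Dict[str, str]
    unit_lengths: Dict[str, int]
    truth: dict
    paths: Optional[Dict[str, Path]] = None


# ---- coordinate arithmetic (generator-owned closed forms) ----


def _gene_geometry(i: int) -> Tuple[str, int, str]:
    chrom = f"chr{i // 2 + 1}"
    offset = GENE_OFFSETS[i % 2]
    strand = "+" if i % 2 == 0 else "-"
    return chrom, offset, strand


def _exons_transcript_order(strand: str) -> List[Tuple[int, int, int, int]]:
    """(t_lo, t_hi, g_lo, g_hi) per exon in transcript order (g rel. offset)."""
    if strand == "+":
        t = 0
        rows = []
        for (g0, g1) in _EXON_G:
            rows.append((t, t + (g1 - g0), g0, g1))
            t += g1 - g0
        return rows
    t = 0
    rows = []
    for (g0, g1) in reversed(_EXON_G):
        rows.append((t, t + (g1 - g0), g0, g1))
        t += g1 - g0
    return rows


def _mature_block_to_genomic(
    offset: int, strand: str, t0: int, t1: int
) -> Tuple[int, int]:
    """Genomic span of a mature-transcript interval contained in one exon."""
    for t_lo, t_hi, g_lo, g_hi in _exons_transcript_order(strand):
        if t_lo <= t0 and t1 <= t_hi:
            if strand == "+":
                return offset + g_lo + (t0 - t_lo), offset + g_lo + (t1 - t_lo)
            return offset + g_hi - (t1 - t_lo), offset + g_hi - (t0 - t_lo)
    raise ValueError(f"interval [{t0},{t1}) not contained in a single exon")


def _transcript_to_premrna(strand: str, t: int) -> int:
    """Shift a mature coordinate by the introns upstream in transcript order."""
    shift = 0
    upstream = INTRON_LENS if strand == "+" else tuple(reversed(INTRON_LENS))
    for (t_lo, t_hi, _, _), up in zip(
        _exons_transcript_order(strand), (0,) + tuple(np.cumsum(upstream))
    ):
        if t_lo <= t < t_hi:
            return t + int(up)
    raise ValueError(f"transcript position {t} out of range")


def _composed_segment(length: int, n_gc: int, rng: np.random.Generator) -> str:
    if not (0 <= n_gc <= length):
        raise ValueError("n_gc out of range")
    bases = [rng.choice(["G", "C"]) for _ in range(n_gc)] + [
        rng.choice(["A", "T"]) for _ in range(length - n_gc)
    ]
    rng.shuffle(bases)
    return "".join(str(b) for b in bases)


def _rand_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---- the generator ----


def make_fixture(
    config: Optional[FixtureConfig] = None,
    seed: int = 0,
    out_dir: Optional[Path] = None,
) -> Fixture:
    """Build the fixture bundle; fully deterministic for a given seed."""
    config = config or FixtureConfig()
    if config.n_genes != 20 or config.n_lnc != 10:
        raise ValueError("the fixture geometry is fixed at 20 genes / 10 lncRNAs")
    rng = np.random.default_rng(seed)

    # 1. random genome
    genome: Dict[str, List[str]] = {
        f"chr{c}": list(_rand_seq(CHROM_LEN, rng)) for c in range(1, 11)
    }
    genome[LNC_CHROM] = list(_rand_seq(LNC_CHROM_LEN, rng))

    # 2. transcript models
    models: List[TranscriptModel] = []
    gene_map: Dict[str, str] = {}
    for i in range(config.n_genes):
        chrom, offset, strand = _gene_geometry(i)
        tid, gid = f"T{i:02d}", f"G{i:02d}"
        exons = tuple(
            GenomicInterval(chrom, offset + g0, offset + g1, strand, tid)
            for g0, g1 in _EXON_G
        )
        coding = i < 16
        cds = None
        if coding:
            g_a, g_b = _mature_block_to_genomic(offset, strand, CDS_T[0], CDS_T[0] + 1)
            g_c, g_d = _mature_block_to_genomic(offset, strand, CDS_T[1] - 1, CDS_T[1])
            lo = min(g_a, g_c)
            hi = max(g_b, g_d)
            cds = (lo, hi)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds,
                biotype="protein_coding" if coding else "noncoding",
            )
        )
        gene_map[tid] = gid
    # skipped-exon isoform of gene G01 (alternative splice sites for exon 2)
    chrom1, off1, strand1 = _gene_geometry(1)
    iso = TranscriptModel(
        transcript_id="T01B",
        gene_id="G01",
        chrom=chrom1,
        strand=strand1,
        exons=(
            GenomicInterval(chrom1, off1 + _EXON_G[0][0], off1 + _EXON_G[0][1], strand1, "T01B"),
            GenomicInterval(chrom1, off1 + _EXON_G[2][0], off1 + _EXON_G[2][1], strand1, "T01B"),
        ),
        cds=None,
        biotype="protein_coding",
    )
    models.append(iso)
    gene_map["T01B"] = "G01"

    model_by_tid = {m.transcript_id: m for m in models}

    # 3. plant composed segments into the genome (target side, with guards)
    plant_segments: Dict[str, str] = {}
    for plant in config.plants:
        model = model_by_tid[plant.target_id]
        i = int(plant.target_id[1:3])
        chrom, offset, strand = _gene_geometry(i)
        if plant.kind == "premrna":
            if strand != "+":
                raise ValueError("premrna plants are supported on + strand genes")
            seg = _composed_segment(
                plant.length // 2, plant.n_gc // 2, rng
            ) + _composed_segment(
                plant.length - plant.length // 2, plant.n_gc - plant.n_gc // 2, rng
            )
            g0 = offset + plant.start
            g1 = g0 + plant.length
            if not (0 <= g0 - GUARD and g1 + GUARD <= len(genome[chrom])):
                raise ValueError(f"plant {plant.name} does not fit its host")
            genome[chrom][g0 - GUARD : g1 + GUARD] = list(
                "A" * GUARD + seg + "A" * GUARD
            )
        else:
            seg = _composed_segment(plant.length, plant.n_gc, rng)
            t0, t1 = plant.start, plant.start + plant.length
            g0, g1 = _mature_block_to_genomic(offset, strand, t0 - GUARD, t1 + GUARD)
            guarded = "A" * GUARD + seg + "A" * GUARD
            genome[chrom][g0:g1] = list(
                guarded if strand == "+" else revcomp(guarded)
            )
        plant_segments[plant.name] = seg

    # 4. lncRNA sequences; nine intergenic plus one natural antisense (LNC09)
    lnc_seqs: Dict[str, List[str]] = {}
    lnc_models: List[TranscriptModel] = []
    for k in range(9):
        lid = f"LNC{k:02d}"
        start = 200 + k * 700
        lnc_seqs[lid] = list(_rand_seq(LNC_LEN, rng))
        lnc_models.append(
            TranscriptModel(
                transcript_id=lid,
                gene_id=f"LG{k:02d}",
                chrom=LNC_CHROM,
                strand="+",
                exons=(GenomicInterval(LNC_CHROM, start, start + LNC_LEN, "+", lid),),
                cds=None,
                biotype="noncoding",
            )
        )
        gene_map[lid] = f"LG{k:02d}"
    for plant in config.plants:
        seq = lnc_seqs[plant.lnc_id]
        off, L = plant.lnc_offset, plant.length
        if off < GUARD or off + L + GUARD > len(seq):
            raise ValueError(f"plant {plant.name} longer than its lncRNA host")
        seq[off - GUARD : off + L + GUARD] = list(
            "A" * GUARD + revcomp(plant_segments[plant.name]) + "A" * GUARD
        )
    for k in range(9):
        lid = f"LNC{k:02d}"
        start = 200 + k * 700
        genome[LNC_CHROM][start : start + LNC_LEN] = lnc_seqs[lid]

    # antisense lncRNA inside the first gene's long intron (chr1, G00 is '+')
    nat_lo, nat_hi = 400, 800
    lnc_models.append(
        TranscriptModel(
            transcript_id="LNC09",
            gene_id="LG09",
            chrom="chr1",
            strand="-",
            exons=(GenomicInterval("chr1", nat_lo, nat_hi, "-", "LNC09"),),
            cds=None,
            biotype="noncoding",
        )
    )
    gene_map["LNC09"] = "LG09"

    genome_str = {c: "".join(s) for c, s in genome.items()}
    lnc_records = [
        SequenceRecord(m.transcript_id, m.mature_sequence(genome_str))
        for m in lnc_models
    ]
    target_records = [
        SequenceRecord(m.transcript_id, m.mature_sequence(genome_str))
        for m in models
    ]

    # 5. truth: planted + natural hits with closed-form coordinates and scores
    mrna_hits = []
    premrna_hits = []
    junction_names = []
    for plant in config.plants:
        i = int(plant.target_id[1:3])
        _, offset, strand = _gene_geometry(i)
        entry = {
            "name": plant.name,
            "lnc_id": plant.lnc_id,
            "target_id": plant.target_id,
            "lnc_start": plant.lnc_offset,
            "lnc_end": plant.lnc_offset + plant.length,
            "score": plant.score,
            "region_class": plant.region_class,
            "locality": "trans",
        }
        if plant.kind == "mature":
            mrna_hits.append(
                dict(entry, target_start=plant.start,
                     target_end=plant.start + plant.length, mode="mRNA")
            )
            p0 = _transcript_to_premrna(strand, plant.start)
            premrna_hits.append(
                dict(entry, target_start=p0, target_end=p0 + plant.length,
                     mode="pre-mRNA")
            )
        else:
            premrna_hits.append(
                dict(entry, target_start=plant.start,
                     target_end=plant.start + plant.length, mode="pre-mRNA")
            )
            junction_names.append(plant.name)

    # natural antisense hits: LNC09 complements the unmasked parts of G00's
    # first intron. Masking (flank f) hides genomic [300+f, 900-f).
    f = config.flank
    mask_lo, mask_hi = 300 + f, 900 - f
    chr1 = genome_str["chr1"]
    g00_offset = 100

    def _wc_score(g_lo: int, g_hi: int) -> int:
        return sum(4 if b in "GC" else 2 for b in chr1[g_lo:g_hi])

    natural = []
    if mask_lo < mask_hi:  # the intron interior is masked; two flank hits
        segs = [(nat_lo, min(nat_hi, mask_lo)), (max(nat_lo, mask_hi), nat_hi)]
    else:
        segs = [(nat_lo, nat_hi)]
    for g_lo, g_hi in segs:
        if g_hi - g_lo <= 0:
            continue
        score = _wc_score(g_lo, g_hi)
        if score < config.threshold_premrna:
            continue
        natural.append(
            {
                "name": f"NAT{g_lo}",
                "lnc_id": "LNC09",
                "target_id": "T00",
                "lnc_start": nat_hi - g_hi,
                "lnc_end": nat_hi - g_lo,
                "target_start": g_lo - g00_offset,
                "target_end": g_hi - g00_offset,
                "score": score,
                "mode": "pre-mRNA",
                "region_class": "CDS",  # the intron sits inside the CDS span
                "locality": "cis",
            }
        )
    premrna_hits.extend(natural)

    # 6. regulatory features; geometry keyed off the truth hit regions
    perturb = config.perturbation
    by_name = {h["name"]: h for h in mrna_hits + premrna_hits}

    def _region_genomic(name: str) -> Tuple[str, int, int, str]:
        h = by_name[name]
        i = int(h["target_id"][1:3])
        chrom, offset, strand = _gene_geometry(i)
        if h["mode"] == "pre-mRNA":
            if strand == "+":
                return chrom, offset + h["target_start"], offset + h["target_end"], strand
            span_hi = offset + GENE_SPAN
            return chrom, span_hi - h["target_end"], span_hi - h["target_start"], strand
        g0, g1 = _mature_block_to_genomic(
            offset, strand, h["target_start"], h["target_end"]
        )
        return chrom, g0, g1, strand

    counts: Dict[str, int] = {}
    clip_sites: List[GenomicInterval] = []
    mirna_predicted: List[GenomicInterval] = []
    mirna_clip: List[GenomicInterval] = []
    alu_elements: List[GenomicInterval] = []
    editing_sites: List[GenomicInterval] = []
    if by_name:
        counts = {"splice_mask": 0, "mirna_mask": 0, "smd": 0, "editing": 0}

    # splice filter (on P4's junction-spanning region)
    if "P4" in by_name:
        c4, r4_lo, r4_hi, s4 = _region_genomic("P4")
        if perturb == "clip_partial":
            clip_pos = GenomicInterval(c4, r4_lo - 10, r4_lo + 20, s4, "clip_pos")
        else:
            clip_pos = GenomicInterval(c4, r4_lo + 15, r4_lo + 35, s4, "clip_pos")
            counts["splice_mask"] += 1
        clip_sites = [
            clip_pos,
            GenomicInterval(c4, r4_lo - 10, r4_lo + 20, s4, "clip_partial_neg"),
            GenomicInterval(c4, r4_lo + 20, r4_lo + 40, "-" if s4 == "+" else "+", "clip_strand_neg"),
            GenomicInterval(c4, 2000, 2020, s4, "clip_far_neg"),
        ]

    # miRNA filter (positive on P2, negative straddling P2's edge)
    if "P2" in by_name:
        c2, r2_lo, r2_hi, s2 = _region_genomic("P2")
        if perturb == "mirna_below_half":
            # intersection [r2_hi-5, r2_hi+9): length 14, only 5 inside
            mirna_predicted = [GenomicInterval(c2, r2_hi - 5, r2_hi + 9, s2, "pred_pos")]
            mirna_clip = [GenomicInterval(c2, r2_hi - 5, r2_hi + 11, s2, "agoclip_pos")]
        else:
            # intersection [r2_lo+18, r2_lo+29): length 11, fully inside
            mirna_predicted = [GenomicInterval(c2, r2_lo + 15, r2_lo + 29, s2, "pred_pos")]
            mirna_clip = [GenomicInterval(c2, r2_lo + 18, r2_lo + 35, s2, "agoclip_pos")]
            counts["mirna_mask"] += 1
        # negative pair: intersection length 18 but only 8 inside the region
        mirna_predicted.append(GenomicInterval(c2, r2_hi - 10, r2_hi + 10, s2, "pred_neg"))
        mirna_clip.append(GenomicInterval(c2, r2_hi - 8, r2_hi + 12, s2, "agoclip_neg"))

    # SMD filter (positive Alu inside P1's region and T02's 3' UTR)
    if "P1" in by_name and "P2" in by_name:
        c1, r1_lo, r1_hi, s1 = _region_genomic("P1")
        if perturb == "alu_outside_utr3":
            alu_pos = GenomicInterval(c2, r2_lo + 10, r2_lo + 50, s2, "alu_pos")  # CDS
        else:
            alu_pos = GenomicInterval(c1, r1_lo + 30, r1_lo + 90, s1, "alu_pos")
            counts["smd"] += 1
        alu_elements = [alu_pos]
        if "P3" in by_name:
            c3, r3_lo, r3_hi, s3 = _region_genomic("P3")
            alu_elements.append(
                GenomicInterval(c3, r3_lo + 10, r3_lo + 30, s3, "alu_cds_straddle_neg")
            )
        if "P5" in by_name:
            c5, r5_lo, r5_hi, s5 = _region_genomic("P5")
            alu_elements.append(
                GenomicInterval(c5, r5_lo + 10, r5_lo + 40, s5, "alu_noncoding_neg")
            )

    # editing filter (positive single base inside P3's region)
    if "P3" in by_name and "P1" in by_name:
        c3, r3_lo, r3_hi, s3 = _region_genomic("P3")
        c1, r1_lo, _, s1 = _region_genomic("P1")
        if perturb == "editing_at_end":
            edit_pos = GenomicInterval(c3, r3_hi, r3_hi + 1, s3, "edit_pos")
        else:
            edit_pos = GenomicInterval(c3, r3_lo + 20, r3_lo + 21, s3, "edit_pos")
            counts["editing"] += 1
        editing_sites = [
            edit_pos,
            GenomicInterval(c3, r3_hi, r3_hi + 1, s3, "edit_end_neg"),
            GenomicInterval(c1, r1_lo + 40, r1_lo + 41, "-" if s1 == "+" else "+", "edit_strand_neg"),
        ]

    # 7. expression design: read counts per (transcript, library)
    read_design = {
        "L1": {"LNC00": 20, "T02": 30, "LNC01": 100, "T04": 2, "LNC04": 10,
               "T01": 5, "LNC05": 5},
        "L2": {"LNC02": 2, "T05": 40, "T16": 10, "T03": 5},
        "L3": {"LNC03": 8, "T06": 12, "LNC06": 4},
    }
    mapping_rows: List[Tuple[str, str, str, int]] = []
    for lib in sorted(read_design):
        for tid in sorted(read_design[lib]):
            for k in range(read_design[lib][tid]):
                mapping_rows.append((f"{lib}_{tid}_{k}", lib, tid, 0))
    # reads exercising the uniqueness rules (library L1)
    for k, tid in enumerate([f"T{i:02d}" for i in range(11)]):
        mapping_rows.append(("r_eleven_hits", "L1", tid, 0))
    mapping_rows.append(("r_isoform_pair", "L1", "T01", 0))
    mapping_rows.append(("r_isoform_pair", "L1", "T01B", 0))
    mapping_rows.append(("r_two_genes", "L1", "T07", 0))
    mapping_rows.append(("r_two_genes", "L1", "T08", 0))
    mapping_rows.append(("r_bad_mismatch", "L1", "T09", 2))

    unit_lengths = {r.id: len(r.seq) for r in target_records + lnc_records}

    # closed-form coexpression / balance truth (transcript level, RPKM > 0)
    pair_lib = {
        ("LNC00", "T02"): "L1",
        ("LNC01", "T04"): "L1",
        ("LNC02", "T05"): "L2",
        ("LNC03", "T06"): "L3",
    }
    coexpression = {}
    balanced = {}
    for h in mrna_hits + premrna_hits:
        key = (h["lnc_id"], h["target_id"])
        name = f"{key[0]}|{key[1]}"
        if key in pair_lib:
            lib = pair_lib[key]
            coexpression[name] = True
            counts_l = read_design[lib][key[0]]
            counts_t = read_design[lib][key[1]]
            r_l = counts_l / unit_lengths[key[0]]
            r_t = counts_t / unit_lengths[key[1]]
            balanced[name] = (r_l / r_t > 1) or (max(r_l, r_t) / min(r_l, r_t) < 10)
        else:
            coexpression[name] = False

    truth = {
        "seed": seed,
        "perturbation": perturb,
        "thresholds": {
            "mRNA": config.threshold_mrna,
            "pre-mRNA": config.threshold_premrna,
        },
        "mrna_hits": mrna_hits,
        "premrna_hits": premrna_hits,
        "junction_hits": [
            h for h in premrna_hits if h["name"] in junction_names
        ],
        "regulatory_counts": counts,
        "coexpression": coexpression,
        "balanced": balanced,
    }

    fixture = Fixture(
        config=config,
        seed=seed,
        genome=genome_str,
        models=models + lnc_models,
        lnc_records=lnc_records,
        target_records=target_records,
        clip_sites=clip_sites,
        mirna_clip=mirna_clip,
        mirna_predicted=mirna_predicted,
        alu_elements=alu_elements,
        editing_sites=editing_sites,
        mapping_rows=mapping_rows,
        gene_map=gene_map,
        unit_lengths=unit_lengths,
        truth=truth,
    )
    if out_dir is not None:
        fixture.paths = write_fixture(fixture, Path(out_dir))
    return fixture


def write_fixture(fixture: Fixture, out_dir: Path) -> Dict[str, Path]:
    """Serialize the bundle as plain-text files; byte-identical per seed."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "annotation": out_dir / "annotation.gtf",
        "lnc": out_dir / "lnc.fa",
        "targets": out_dir / "targets.fa",
        "clip": out_dir / "clip.bed",
        "mirna_clip": out_dir / "mirna_clip.bed",
        "mirna_predicted": out_dir / "mirna_predicted.bed",
        "alu": out_dir / "alu.bed",
        "editing": out_dir / "editing.bed",
        "mappings": out_dir / "mappings.tsv",
        "truth": out_dir / "truth.json",
    }
    write_fasta(
        [SequenceRecord(c, s) for c, s in sorted(fixture.genome.items())],
        paths["genome"],
    )
    write_gtf(fixture.models, paths["annotation"])
    write_fasta(fixture.lnc_records, paths["lnc"])
    write_fasta(fixture.target_records, paths["targets"])
    write_bed(fixture.clip_sites, paths["clip"])
    write_bed(fixture.mirna_clip, paths["mirna_clip"])
    write_bed(fixture.mirna_predicted, paths["mirna_predicted"])
    write_bed(fixture.alu_elements, paths["alu"])
    write_bed(fixture.editing_sites, paths["editing"])
    with open(paths["mappings"], "w", encoding="utf-8") as out:
        for row in fixture.mapping_rows:
            out.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["truth"], "w", encoding="utf-8") as out:
        json.dump(fixture.truth, out, indent=1, sort_keys=True)
        out.write("\n")
    return paths


# ---- truth comparison ----


def _hit_key(h) -> Tuple:
    if isinstance(h, dict):
        return (
            h["lnc_id"], h["target_id"], h["lnc_start"], h["lnc_end"],
            h["target_start"], h["target_end"], h["score"],
        )
    return (
        h.lnc_id, h.target_id, h.lnc_interval[0], h.lnc_interval[1],
        h.target_interval[0], h.target_interval[1], h.score,
    )


def truth_check(outputs: Mapping[str, object], truth: Mapping[str, object]) -> dict:
    """Compare pipeline outputs against the truth table, stage by stage.

    ``outputs`` must provide every stage the truth table lists among
    mrna_hits / premrna_hits / junction_hits (as DuplexAlignment lists or
    dicts), regulatory_counts and coexpression. Returns a report with one
    entry per stage and an overall ``pass`` flag.
    """
    report = {"stages": {}, "pass": True}
    for stage in ("mrna_hits", "premrna_hits", "junction_hits"):
        if stage not in truth:
            continue
        if stage not in outputs:
            raise KeyError(f"missing stage output {stage!r}")
        expected = sorted(_hit_key(h) for h in truth[stage])
        observed = sorted(_hit_key(h) for h in outputs[stage])
        ok = expected == observed
        report["stages"][stage] = {
            "pass": ok,
            "expected": expected,
            "observed": observed,
        }
        report["pass"] &= ok
    for stage in ("regulatory_counts", "coexpression", "balanced"):
        if stage not in truth or stage not in outputs:
            if stage in truth and stage not in outputs and stage != "balanced":
                raise KeyError(f"missing stage output {stage!r}")
            continue
        expected = dict(truth[stage])
        observed = {k: outputs[stage][k] for k in expected if k in outputs[stage]}
        ok = expected == dict(observed) and len(observed) == len(expected)
        report["stages"][stage] = {
            "pass": ok,
            "expected": expected,
            "observed": dict(observed),
        }
        report["pass"] &= ok
    report["pass"] = bool(report["pass"])
    return report
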