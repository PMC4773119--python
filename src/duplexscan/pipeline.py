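"""End-to-end orchestration: find -> project -> classify -> annotate -> expression.

A single config (dict or YAML file) names the inputs and the search mode;
the pipeline runs the duplex search, projects hits to the genome, merges and
classifies interaction regions, applies whichever regulatory filters have
inputs configured, and attaches expression support. Outputs are deterministic
for a given config: a MAF of alignments, a BED of merged interaction regions,
an annotation table, a co-expression report and a manifest carrying the tool
version, config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import yaml

from . import __version__
from .duplex_align import DuplexAlignment, search_transcriptome
from .expression import (
    compute_expression,
    coexpressed,
    expression_balanced,
    read_mappings_tsv,
)
from .formats_io import (
    GenomicInterval,
    PathLike,
    SequenceRecord,
    read_bed,
    read_fasta,
    write_bed,
    write_maf,
)
from .genome_coords import InteractionRecord, build_interaction, gene_span, merge_regions
from .premrna import TranscriptModel, build_premrna_query, read_gtf, spans_junction
from .regulatory import (
    RegulatoryAnnotation,
    editing_candidates,
    intersect_site_sets,
    mirna_mask_candidates,
    smd_candidates,
    splice_mask_candidates,
)
from .scoring import (
    DEFAULT_THRESHOLD_MRNA,
    DEFAULT_THRESHOLD_PREMRNA,
    default_matrix,
    matrix_from_table,
)

logger = logging.getLogger(__name__)

_MODES = ("mRNA", "pre-mRNA")


def _require_path(config: Mapping, key: str) -> Path:
    if key not in config or config[key] is None:
        raise ValueError(f"config is missing required input {key!r}")
    path = Path(config[key])
    if not path.exists():
        raise FileNotFoundError(f"input {key!r}: no such file {path}")
    return path


def _optional_path(config: Mapping, key: str) -> Optional[Path]:
    if key not in config or config[key] is None:
        return None
    path = Path(config[key])
    if not path.exists():
        raise FileNotFoundError(f"input {key!r}: no such file {path}")
    return path


def _config_hash(config: Mapping) -> str:
    # the output location is not an input: identical analyses hash identically
    canon = json.dumps(
        {k: str(v) for k, v in sorted(config.items()) if k != "out_dir"},
        sort_keys=True,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(source: Union[Mapping, PathLike]) -> Dict:
    if isinstance(source, Mapping):
        return dict(source)
    with open(source, encoding="utf-8") as handle:
        loaded = yaml.safe_load(handle)
    if not isinstance(loaded, dict):
        raise ValueError(f"config file {source} does not hold a mapping")
    return loaded


def run_pipeline(config: Union[Mapping, PathLike]) -> Dict:
    """Run the full flow for one mode; returns the in-memory result bundle.

    Config keys: mode (mRNA | pre-mRNA), lnc_fasta, target_fasta, annotation;
    genome_fasta (pre-mRNA mode); optional clip_bed, mirna_clip_bed +
    mirna_predicted_bed (or pre-intersected mirna_sites_bed), alu_bed,
    editing_bed, mappings_tsv, matrix_file, threshold, flank, seed, out_dir.
    """
    config = load_config(config)
    mode = config.get("mode", "mRNA")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")

    matrix = default_matrix()
    matrix_file = _optional_path(config, "matrix_file")
    if matrix_file is not None:
        matrix = matrix_from_table(matrix_file.read_text())
    threshold = int(
        config.get(
            "threshold",
            DEFAULT_THRESHOLD_MRNA if mode == "mRNA" else DEFAULT_THRESHOLD_PREMRNA,
        )
    )
    flank = int(config.get("flank", 250))
    seed = int(config.get("seed", 0))

    lnc_records = read_fasta(_require_path(config, "lnc_fasta"))
    target_records = read_fasta(_require_path(config, "target_fasta"))
    models = read_gtf(_require_path(config, "annotation"))
    model_by_tid = {m.transcript_id: m for m in models}
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    gene_spans = {gid: gene_span(ms) for gid, ms in by_gene.items()}

    if mode == "pre-mRNA":
        genome_path = config.get("genome_fasta")
        if not genome_path:
            raise ValueError("pre-mRNA mode requires genome_fasta in the config")
        genome = {r.id: r.seq for r in read_fasta(_require_path(config, "genome_fasta"))}
        targets = [
            build_premrna_query(model_by_tid[rec.id], genome, flank=flank)[0]
            for rec in target_records
        ]
    else:
        targets = target_records

    logger.info(
        "searching %d lncRNAs vs %d targets (mode=%s, threshold=%d)",
        len(lnc_records), len(targets), mode, threshold,
    )
    hits = search_transcriptome(lnc_records, targets, matrix, threshold, mode=mode)

    junction_hits: List[DuplexAlignment] = []
    if mode == "pre-mRNA":
        junction_hits = [
            h for h in hits if spans_junction(h, model_by_tid[h.target_id])
        ]

    def _interaction(h: DuplexAlignment) -> InteractionRecord:
        lnc_model = model_by_tid[h.lnc_id]
        target_model = model_by_tid[h.target_id]
        return build_interaction(
            h, lnc_model, target_model,
            lnc_gene_span=gene_spans[lnc_model.gene_id],
            target_gene_span=gene_spans[target_model.gene_id],
        )

    # regions of regulatory interest: all mRNA hits, junction-spanning pre-mRNA hits
    focus_hits = hits if mode == "mRNA" else junction_hits
    interactions = [_interaction(h) for h in focus_hits]

    annotations: List[RegulatoryAnnotation] = []
    if mode == "pre-mRNA":
        clip_path = _optional_path(config, "clip_bed")
        if clip_path is not None:
            annotations.extend(
                splice_mask_candidates(interactions, read_bed(clip_path), models)
            )
    else:
        sites_path = _optional_path(config, "mirna_sites_bed")
        clip_path = _optional_path(config, "mirna_clip_bed")
        pred_path = _optional_path(config, "mirna_predicted_bed")
        mirna_sites: Optional[List[GenomicInterval]] = None
        if sites_path is not None:
            mirna_sites = read_bed(sites_path)
        elif clip_path is not None and pred_path is not None:
            mirna_sites = intersect_site_sets(read_bed(clip_path), read_bed(pred_path))
        if mirna_sites is not None:
            annotations.extend(mirna_mask_candidates(interactions, mirna_sites))
        alu_path = _optional_path(config, "alu_bed")
        if alu_path is not None:
            annotations.extend(
                smd_candidates(interactions, read_bed(alu_path), models)
            )
        editing_path = _optional_path(config, "editing_bed")
        if editing_path is not None:
            annotations.extend(
                editing_candidates(interactions, read_bed(editing_path))
            )
    regulatory_counts = {
        m: sum(1 for a in annotations if a.mechanism == m)
        for m in ("splice_mask", "mirna_mask", "smd", "editing")
    }

    coexpression: Dict[str, bool] = {}
    balanced: Dict[str, bool] = {}
    mappings_path = _optional_path(config, "mappings_tsv")
    table = None
    if mappings_path is not None:
        mappings = read_mappings_tsv(mappings_path)
        unit_lengths = {r.id: len(r.seq) for r in lnc_records + target_records}
        gene_map = {m.transcript_id: m.gene_id for m in models}
        table = compute_expression(mappings, unit_lengths, gene_map, level="transcript")
        min_rpkm = float(config.get("min_rpkm", 0.0))
        pairs = sorted({(h.lnc_id, h.target_id) for h in hits})
        for lnc_id, target_id in pairs:
            name = f"{lnc_id}|{target_id}"
            co = coexpressed((lnc_id, target_id), table, min_rpkm=min_rpkm)
            coexpression[name] = co
            if co:
                balanced[name] = any(
                    table.rpkm(lnc_id, lib) > 0
                    and table.rpkm(target_id, lib) > 0
                    and expression_balanced((lnc_id, target_id), table, lib)
                    for lib in table.libraries
                )

    results = {
        "mode": mode,
        "threshold": threshold,
        "alignments": hits,
        "junction_hits": junction_hits,
        "interactions": interactions,
        "annotations": annotations,
        "regulatory_counts": regulatory_counts,
        "coexpression": coexpression,
        "balanced": balanced,
        "expression_table": table,
        "manifest": {
            "tool": "duplexscan",
            "version": __version__,
            "mode": mode,
            "threshold": threshold,
            "seed": seed,
            "config_hash": _config_hash(config),
            "n_alignments": len(hits),
            "n_junction_hits": len(junction_hits),
            "regulatory_counts": regulatory_counts,
        },
    }

    out_dir = config.get("out_dir")
    if out_dir:
        write_outputs(results, Path(out_dir))
    return results


def write_outputs(results: Mapping, out_dir: Path) -> Dict[str, Path]:
    """Serialize a pipeline result bundle; file contents are reproducible."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hits": out_dir / "hits.maf",
        "interactions": out_dir / "interactions.bed",
        "annotations": out_dir / "annotations.tsv",
        "coexpression": out_dir / "coexpression.tsv",
        "manifest": out_dir / "manifest.json",
    }
    write_maf(results["alignments"], paths["hits"])
    if results["mode"] == "pre-mRNA":
        paths["junction_hits"] = out_dir / "junction_hits.maf"
        write_maf(results["junction_hits"], paths["junction_hits"])

    bed_rows: List[GenomicInterval] = []
    for inter in results["interactions"]:
        a = inter.alignment
        for frag in merge_regions(inter.target_genomic):
            bed_rows.append(
                GenomicInterval(
                    frag.chrom, frag.start, frag.end, frag.strand,
                    f"{a.lnc_id}|{a.target_id}|{inter.region_class}|{inter.locality}",
                    float(a.score),
                )
            )
    write_bed(bed_rows, paths["interactions"])

    with open(paths["annotations"], "w", encoding="utf-8") as out:
        out.write("interaction_id\tmechanism\tevidence\tsplice_site_class\n")
        for ann in results["annotations"]:
            evid = ",".join(
                f"{e.chrom}:{e.start}-{e.end}:{e.strand}" for e in ann.evidence
            )
            out.write(
                f"{ann.interaction.interaction_id}\t{ann.mechanism}\t{evid}\t"
                f"{ann.splice_site_class or '.'}\n"
            )

    with open(paths["coexpression"], "w", encoding="utf-8") as out:
        out.write("lnc_id\ttarget_id\tcoexpressed\tbalanced\n")
        for name in sorted(results["coexpression"]):
            lnc_id, target_id = name.split("|")
            co = results["coexpression"][name]
            bal = results["balanced"].get(name)
            out.write(
                f"{lnc_id}\t{target_id}\t{int(co)}\t"
                f"{'.' if bal is None else int(bal)}\n"
            )

    with open(paths["manifest"], "w", encoding="utf-8") as out:
        json.dump(results["manifest"], out, indent=1, sort_keys=True)
        out.write("\n")
    return paths
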