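"""Unique-read RPKM expression support for predicted interactions.

Read mapping itself happens upstream; this module consumes per-read mapping
summaries and applies the uniqueness rules: a read mapping to more than ten
positions is discarded; a read whose hits touch more than one gene is
discarded; transcript-level counting additionally requires exactly one hit.
RPKM = count / (length_nt / 1000) / (library_total / 1e6), with the library
total taken as the unique-surviving read count of that library at the chosen
level. An interaction is expression-supported when both molecules are
expressed in at least one common library, and expression-balanced in a
library when either the two RPKM values differ by less than ten-fold or the
lncRNA is the more abundant molecule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .formats_io import PathLike, _open_text

MAX_MAPPING_POSITIONS = 10
MAX_MISMATCHES = 1


@dataclass(frozen=True)
class MappingSummary:
    """All mapping hits of one read in one library."""

    read_id: str
    library_id: str
    hits: Tuple[Tuple[str, int], ...]  # (transcript_id, mismatches)

    def __post_init__(self) -> None:
        if not self.hits:
            raise ValueError(f"read {self.read_id}: empty hit list")
        if any(mm < 0 for _, mm in self.hits):
            raise ValueError(f"read {self.read_id}: negative mismatch count")


def read_mappings_tsv(path: PathLike) -> List[MappingSummary]:
    """Read the 4-column mapping summary TSV.

    Columns: read_id, library_id, transcript_id, mismatches — one row per
    mapping position.
    """
    grouped: Dict[Tuple[str, str], List[Tuple[str, int]]] = {}
    order: List[Tuple[str, str]] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            key = (fields[0], fields[1])
            if key not in grouped:
                grouped[key] = []
                order.append(key)
            grouped[key].append((fields[2], int(fields[3])))
    return [
        MappingSummary(read_id=r, library_id=l, hits=tuple(grouped[(r, l)]))
        for r, l in order
    ]


def filter_unique(
    mappings: Iterable[MappingSummary],
    level: str = "transcript",
    gene_map: Optional[Mapping[str, str]] = None,
) -> Dict[Tuple[str, str], int]:
    """Unique-read counts per (unit, library) at transcript or gene level.

    Hits exceeding the mismatch allowance are dropped with a warning (they
    should not have survived the upstream mapper). A read counts at gene
    level iff it has at most ten surviving positions, all within one gene;
    at transcript level it must additionally have exactly one hit.
    """
    if level not in ("transcript", "gene"):
        raise ValueError(f"unknown level {level!r}")
    if gene_map is None:
        raise ValueError("gene_map is required")
    counts: Dict[Tuple[str, str], int] = {}
    warned = False
    for rec in mappings:
        hits = [(t, mm) for t, mm in rec.hits if mm <= MAX_MISMATCHES]
        if len(hits) < len(rec.hits) and not warned:
            warnings.warn(
                "dropping mapping records with more than "
                f"{MAX_MISMATCHES} mismatch(es)",
                stacklevel=2,
            )
            warned = True
        if not hits or len(hits) > MAX_MAPPING_POSITIONS:
            continue
        genes = set()
        for t, _ in hits:
            if t not in gene_map:
                raise KeyError(f"transcript {t!r} missing from gene_map")
            genes.add(gene_map[t])
        if len(genes) > 1:
            continue
        if level == "transcript":
            if len(hits) != 1:
                continue
            unit = hits[0][0]
        else:
            unit = next(iter(genes))
        key = (unit, rec.library_id)
        counts[key] = counts.get(key, 0) + 1
    return counts


def rpkm(unique_count: int, transcript_length_nt: int, library_unique_total: int) -> float:
    """Reads per kilobase per million uniquely mapped reads."""
    if transcript_length_nt <= 0:
        raise ValueError("transcript length must be positive")
    if library_unique_total <= 0:
        raise ValueError("library total must be positive")
    return unique_count / (transcript_length_nt / 1000.0) / (library_unique_total / 1e6)


class ExpressionTable:
    """Per-unit, per-library RPKM matrix from uniquely mapped reads."""

    def __init__(self, rpkm_frame: pd.DataFrame, library_totals: Dict[str, int]):
        self.rpkm_frame = rpkm_frame
        self.library_totals = dict(library_totals)

    @property
    def units(self) -> List[str]:
        return list(self.rpkm_frame.index)

    @property
    def libraries(self) -> List[str]:
        return list(self.rpkm_frame.columns)

    def rpkm(self, unit: str, library: str) -> float:
        if unit not in self.rpkm_frame.index:
            raise KeyError(f"unknown unit {unit!r}")
        if library not in self.rpkm_frame.columns:
            raise KeyError(f"unknown library {library!r}")
        return float(self.rpkm_frame.at[unit, library])

    def expressed_units(self, min_rpkm: float = 0.0) -> set:
        mask = (self.rpkm_frame > min_rpkm).any(axis=1)
        return set(self.rpkm_frame.index[mask])

    def to_tsv(self, path: PathLike) -> None:
        frame = self.rpkm_frame.copy()
        frame.index.name = "unit"
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: PathLike, library_totals: Dict[str, int]) -> "ExpressionTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame, library_totals)


def compute_expression(
    mappings: Sequence[MappingSummary],
    unit_lengths: Mapping[str, int],
    gene_map: Mapping[str, str],
    level: str = "transcript",
) -> ExpressionTable:
    """Build the RPKM table; units absent from the counts get zero rows.

    Library totals are the unique-surviving read counts at the chosen level.
    """
    counts = filter_unique(mappings, level=level, gene_map=gene_map)
    libraries = sorted({lib for _, lib in counts} | {m.library_id for m in mappings})
    units = sorted(unit_lengths)
    totals = {lib: 0 for lib in libraries}
    for (_, lib), c in counts.items():
        totals[lib] += c
    frame = pd.DataFrame(0.0, index=units, columns=libraries)
    for (unit, lib), c in counts.items():
        if unit not in unit_lengths:
            raise KeyError(f"unit {unit!r} missing from unit_lengths")
        frame.at[unit, lib] = rpkm(c, unit_lengths[unit], totals[lib])
    return ExpressionTable(frame, totals)


def _interaction_ids(interaction) -> Tuple[str, str]:
    if hasattr(interaction, "alignment"):
        return interaction.alignment.lnc_id, interaction.alignment.target_id
    if hasattr(interaction, "lnc_id"):
        return interaction.lnc_id, interaction.target_id
    lnc_id, target_id = interaction
    return lnc_id, target_id


def coexpressed(interaction, table: ExpressionTable, min_rpkm: float = 0.0) -> bool:
    """True iff both molecules exceed ``min_rpkm`` in at least one common library."""
    lnc_id, target_id = _interaction_ids(interaction)
    for unit in (lnc_id, target_id):
        if unit not in table.rpkm_frame.index:
            raise KeyError(f"unknown transcript {unit!r}")
    row_l = table.rpkm_frame.loc[lnc_id]
    row_t = table.rpkm_frame.loc[target_id]
    return bool(((row_l > min_rpkm) & (row_t > min_rpkm)).any())


def expression_balanced(interaction, table: ExpressionTable, library: str) -> bool:
    """Balance rule in one library: <10-fold difference, or lncRNA in excess."""
    lnc_id, target_id = _interaction_ids(interaction)
    r_lnc = table.rpkm(lnc_id, library)
    r_tgt = table.rpkm(target_id, library)
    if r_lnc <= 0 or r_tgt <= 0:
        raise ValueError(
            f"expression_balanced requires both molecules expressed in {library!r}"
        )
    if r_lnc / r_tgt > 1:
        return True
    return max(r_lnc, r_tgt) / min(r_lnc, r_tgt) < 10
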