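"""Readers and writers for the plain-text formats the pipeline speaks.

All genomic intervals are 0-based half-open (BED convention) everywhere in
memory; conversions to/from 1-based formats happen only at the file boundary.
Sequences are stored in the DNA alphabet: U is folded to T on input and N is a
legal character (it is how intron interiors are masked). Gzip-compressed input
is handled transparently for every reader.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Optional, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the overlap with ``other`` (same chrom assumed)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record needs a non-empty id")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def normalize_sequence(raw: str) -> str:
    """Upper-case and fold U to T; validation happens in SequenceRecord."""
    return raw.upper().replace("U", "T")


def read_fasta(path: PathLike) -> List[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into normalized records.

    Ids must be unique and sequences non-empty; U is normalized to T and
    lowercase is folded to uppercase.
    """
    records: List[SequenceRecord] = []
    seen = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, normalize_sequence(str(rec.seq))))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Read a 3-6 column BED file.

    Strand defaults to '+' (with a logged warning) when the file has fewer
    than six columns. Malformed intervals raise with the offending line number.
    """
    intervals: List[GenomicInterval] = []
    warned = False
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            if len(fields) > 5:
                strand = fields[5]
            else:
                strand = "+"
                if not warned:
                    logger.warning(
                        "%s:%d: no strand column, defaulting to '+'", path, lineno
                    )
                    warned = True
            intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# MAF dialect
#
# One block per duplex alignment:
#
#   a score=<int> mode=<mRNA|pre-mRNA>
#   s <lnc_id>    <start> <size> + <srcSize> <text>
#   s <target_id> <start> <size> - <srcSize> <text>
#
# The query (lncRNA) line is given on its plus orientation; the target line
# follows MAF minus-strand semantics: the start is counted on the
# reverse-complemented target and the text shows reverse-complement bases, so
# that the two text rows pair column by column (an antiparallel duplex).
# ---------------------------------------------------------------------------

MAF_HEADER = "##maf version=1 scoring=duplexscan"


def write_maf(alignments: Iterable["DuplexAlignment"], path: PathLike) -> None:  # noqa: F821
    """Write duplex alignments as MAF blocks; empty input gives a header-only file."""
    with open(path, "w", encoding="utf-8") as out:
        out.write(MAF_HEADER + "\n\n")
        for aln in alignments:
            q_text = "".join(qc for qc, _ in aln.columns)
            t_text = "".join(
                "-" if tc == "-" else tc.translate(_COMPLEMENT) for _, tc in aln.columns
            )
            q_size = sum(1 for qc, _ in aln.columns if qc != "-")
            t_size = sum(1 for _, tc in aln.columns if tc != "-")
            t_start_rc = aln.target_length - aln.target_interval[1]
            out.write(f"a score={aln.score} mode={aln.mode}\n")
            out.write(
                f"s {aln.lnc_id} {aln.lnc_interval[0]} {q_size} + "
                f"{aln.lnc_length} {q_text}\n"
            )
            out.write(
                f"s {aln.target_id} {t_start_rc} {t_size} - "
                f"{aln.target_length} {t_text}\n"
            )
            out.write("\n")


def _parse_maf_s_line(line: str, path: PathLike, lineno: int):
    fields = line.split()
    if len(fields) != 7:
        raise ValueError(f"{path}:{lineno}: malformed MAF 's' line")
    _, name, start, size, strand, src_size, text = fields
    return name, int(start), int(size), strand, int(src_size), text


def read_maf(path: PathLike) -> List["DuplexAlignment"]:  # noqa: F821
    """Parse the duplexscan MAF dialect back into DuplexAlignment records."""
    from .duplex_align import DuplexAlignment

    alignments: List[DuplexAlignment] = []
    with _open_text(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if not line or line.startswith("#"):
            i += 1
            continue
        if not line.startswith("a"):
            raise ValueError(f"{path}:{i + 1}: expected 'a' line, got {line!r}")
        attrs = dict(
            kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
        )
        if "score" not in attrs:
            raise ValueError(f"{path}:{i + 1}: MAF block lacks score")
        score = int(attrs["score"])
        mode = attrs.get("mode", "mRNA")
        if i + 2 >= n:
            raise ValueError(f"{path}:{i + 1}: truncated MAF block")
        lnc_id, q_start, q_size, q_strand, q_src, q_text = _parse_maf_s_line(
            lines[i + 1], path, i + 2
        )
        tgt_id, t_start_rc, t_size, t_strand, t_src, t_text = _parse_maf_s_line(
            lines[i + 2], path, i + 3
        )
        if q_strand != "+" or t_strand != "-":
            raise ValueError(f"{path}:{i + 1}: unexpected strand layout")
        if len(q_text) != len(t_text):
            raise ValueError(f"{path}:{i + 1}: ragged MAF block")
        columns = tuple(
            (qc, tc if tc == "-" else tc.translate(_COMPLEMENT))
            for qc, tc in zip(q_text, t_text)
        )
        alignments.append(
            DuplexAlignment(
                lnc_id=lnc_id,
                target_id=tgt_id,
                lnc_interval=(q_start, q_start + q_size),
                target_interval=(t_src - t_start_rc - t_size, t_src - t_start_rc),
                score=score,
                columns=columns,
                lnc_length=q_src,
                target_length=t_src,
                mode=mode,
            )
        )
        i += 3
    return alignments
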