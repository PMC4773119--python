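"""Local antiparallel duplex search between a lncRNA and a target RNA.

The biological question — where can two RNAs hybridize — is turned into a
string alignment by aligning the query against the reverse complement of the
target: a G:C duplex pair becomes a (G,G) identity in the transformed space,
A:T becomes (A,A), and the G:U wobble maps to the off-diagonal (G,A) and
(T,C) cells. High-scoring local alignments of the transformed problem are
mapped back to antiparallel duplex coordinates on the target's own 5'->3'
axis (ascending query positions pair with descending target positions).

Two search entry points share one extraction engine:

* :func:`align_duplex_exact` — exhaustive affine-gap DP; returns every
  locally maximal, mutually non-overlapping duplex scoring at least
  ``min_score``, extracted greedily by descending score.
* :func:`align_duplex_seeded` — the production search. Wobble-free
  (Watson-Crick) seed matches gate the expensive work: below a search-space
  cutoff the exhaustive DP runs as-is (the two functions then agree exactly);
  above it, window-bounded exhaustive DP runs around each seed cluster. A
  pair with no perfect complementary run of ``seed_len`` is never aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._dp import MASK_CODE, N_SYMBOLS, encode, fill_matrices, best_score_only, traceback
from .formats_io import SequenceRecord, write_maf
from .scoring import PairingMatrix, pair_score

#: Hard cap on DP matrix size (cells); guards memory on the exact path.
MAX_DP_CELLS = 6_250_000

#: Below this |q|*|t| the seeded search simply runs the exhaustive DP.
DEFAULT_EXHAUSTIVE_CELLS = 640_000

DEFAULT_SEED_LEN = 10
DEFAULT_WINDOW = 400

_CODE_TO_BASE = "ACGTN?"
_COMP_CODE = np.array([3, 2, 1, 0, 4, MASK_CODE], dtype=np.int8)


@dataclass(frozen=True)
class DuplexAlignment:
    """A scored antiparallel base-pairing between a lncRNA and a target RNA.

    Intervals are 0-based half-open on each molecule's 5'->3' axis. ``columns``
    lists (query_base_or_gap, target_base_or_gap) pairs in ascending query
    order; the paired target positions descend (antiparallel hybridization).
    """

    lnc_id: str
    target_id: str
    lnc_interval: Tuple[int, int]
    target_interval: Tuple[int, int]
    score: int
    columns: Tuple[Tuple[str, str], ...]
    lnc_length: int
    target_length: int
    mode: str = "mRNA"


def _substitution_table(matrix: PairingMatrix) -> np.ndarray:
    """6x6 transformed-space table: sub[a, b] = pair_score(a, complement(b))."""
    sub = np.full((N_SYMBOLS, N_SYMBOLS), np.int32(-(10**7)), dtype=np.int32)
    bases = "ACGTN"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    for ai, a in enumerate(bases):
        for bi, b in enumerate(bases):
            sub[ai, bi] = pair_score(matrix, a, comp[b])
    return sub


def _transform_target(t: str) -> np.ndarray:
    """Encode the reverse complement of the target."""
    return _COMP_CODE[encode(t)][::-1].copy()


def _iter_local_duplexes(
    q_arr: np.ndarray,
    tp_arr: np.ndarray,
    sub: np.ndarray,
    go: int,
    ge: int,
    min_score: int,
) -> List[Tuple[int, int, int, int, int, np.ndarray]]:
    """Greedy extraction of non-overlapping locally maximal alignments.

    Returns (score, i0, i1, j0, j1, ops) tuples in extraction (descending
    score) order; coordinates are on the transformed axes. The footprint of
    each extracted alignment is masked on both molecules before re-running, so
    reported alignments never share positions on either molecule.
    """
    nq, nt = len(q_arr), len(tp_arr)
    if (nq + 1) * (nt + 1) > MAX_DP_CELLS:
        raise ValueError(
            f"DP matrix of {nq}x{nt} exceeds the exact-search cap; "
            "use align_duplex_seeded for sequences this long"
        )
    q = q_arr.copy()
    tp = tp_arr.copy()
    shape = (nq + 1, nt + 1)
    M = np.empty(shape, dtype=np.int32)
    Ix = np.empty(shape, dtype=np.int32)
    Iy = np.empty(shape, dtype=np.int32)
    out = []
    min_score = max(int(min_score), 1)
    while True:
        best = fill_matrices(q, tp, sub, np.int32(go), np.int32(ge), M, Ix, Iy)
        if best < min_score:
            break
        ends = np.argwhere(M == best)
        candidates = []
        for i_end, j_end in ends:
            i0, j0, ops = traceback(
                int(i_end), int(j_end), q, tp, sub, np.int32(go), np.int32(ge), M, Ix, Iy
            )
            candidates.append((i0, int(i_end), j0, int(j_end), ops))
        # smallest (lnc_start, target_start): target_start descends with j1
        candidates.sort(key=lambda c: (c[0], -c[3], c[1], -c[2]))
        i0, i1, j0, j1, ops = candidates[0]
        out.append((int(best), i0, i1, j0, j1, ops))
        q[i0:i1] = MASK_CODE
        tp[j0:j1] = MASK_CODE
    return out


def _columns_from_ops(
    q: str, t: str, i0: int, j0: int, ops: np.ndarray
) -> Tuple[Tuple[str, str], ...]:
    """Rebuild duplex columns (actual bases of both molecules) from DP ops."""
    cols = []
    i, j = i0, j0
    t_len = len(t)
    for op in ops:
        if op == 0:
            cols.append((q[i], t[t_len - 1 - j]))
            i += 1
            j += 1
        elif op == 1:  # gap in target, consumes query
            cols.append((q[i], "-"))
            i += 1
        else:  # gap in query, consumes target
            cols.append(("-", t[t_len - 1 - j]))
            j += 1
    return tuple(cols)


def _build_alignments(
    q: SequenceRecord,
    t: SequenceRecord,
    raw: Iterable[Tuple[int, int, int, int, int, np.ndarray]],
    mode: str,
) -> List[DuplexAlignment]:
    t_len = len(t.seq)
    alignments = []
    for score, i0, i1, j0, j1, ops in raw:
        alignments.append(
            DuplexAlignment(
                lnc_id=q.id,
                target_id=t.id,
                lnc_interval=(i0, i1),
                target_interval=(t_len - j1, t_len - j0),
                score=score,
                columns=_columns_from_ops(q.seq, t.seq, i0, j0, ops),
                lnc_length=len(q.seq),
                target_length=t_len,
                mode=mode,
            )
        )
    alignments.sort(key=lambda a: (-a.score, a.lnc_interval, a.target_interval))
    return alignments


def align_duplex_exact(
    q: SequenceRecord,
    t: SequenceRecord,
    matrix: PairingMatrix,
    min_score: int,
    mode: str = "mRNA",
) -> List[DuplexAlignment]:
    """Exhaustive-DP duplex search (the oracle; quadratic time and memory).

    Returns all maximal-scoring, mutually non-overlapping local duplexes with
    score >= ``min_score``, greedily by descending score; ties broken towards
    the smaller (lnc_start, target_start).
    """
    if not q.seq or not t.seq:
        raise ValueError("empty sequence")
    sub = _substitution_table(matrix)
    raw = _iter_local_duplexes(
        encode(q.seq), _transform_target(t.seq), sub,
        matrix.gap_open, matrix.gap_extend, min_score,
    )
    return _build_alignments(q, t, raw, mode)


def best_duplex_score(q_seq: str, t_seq: str, matrix: PairingMatrix) -> int:
    """Best local duplex score only (linear memory; used by calibration)."""
    sub = _substitution_table(matrix)
    return int(
        best_score_only(
            encode(q_seq), _transform_target(t_seq), sub,
            np.int32(matrix.gap_open), np.int32(matrix.gap_extend),
        )
    )


def _find_seeds(q_arr: np.ndarray, tp_arr: np.ndarray, seed_len: int) -> List[Tuple[int, int]]:
    """Exact Watson-Crick complementary runs of ``seed_len``.

    In transformed space a WC pair is an identity over A/C/G/T, so seeds are
    plain exact k-mer matches (N and mask codes excluded).
    """
    kmers: Dict[bytes, List[int]] = {}
    qb = q_arr.tobytes()
    tb = tp_arr.tobytes()
    valid_q = q_arr < 4
    # positions where a clean ACGT k-mer starts
    run_ok = np.ones(len(q_arr) - seed_len + 1, dtype=bool) if len(q_arr) >= seed_len else np.zeros(0, dtype=bool)
    for off in range(seed_len):
        run_ok &= valid_q[off : off + len(run_ok)]
    for i in np.nonzero(run_ok)[0]:
        kmers.setdefault(qb[i : i + seed_len], []).append(int(i))
    seeds = []
    if len(tp_arr) >= seed_len:
        valid_t = tp_arr < 4
        t_ok = np.ones(len(tp_arr) - seed_len + 1, dtype=bool)
        for off in range(seed_len):
            t_ok &= valid_t[off : off + len(t_ok)]
        for j in np.nonzero(t_ok)[0]:
            for i in kmers.get(tb[j : j + seed_len], ()):
                seeds.append((i, int(j)))
    return seeds


def _cluster_windows(
    seeds: Sequence[Tuple[int, int]], seed_len: int, window: int, nq: int, nt: int
) -> List[Tuple[int, int, int, int]]:
    """Merge per-seed windows that overlap in both dimensions into boxes."""
    boxes: List[List[int]] = []
    for i, j in sorted(seeds):
        qi0, qi1 = max(0, i - window), min(nq, i + seed_len + window)
        tj0, tj1 = max(0, j - window), min(nt, j + seed_len + window)
        merged = False
        for box in boxes:
            if qi0 < box[1] and box[0] < qi1 and tj0 < box[3] and box[2] < tj1:
                box[0], box[1] = min(box[0], qi0), max(box[1], qi1)
                box[2], box[3] = min(box[2], tj0), max(box[3], tj1)
                merged = True
                break
        if not merged:
            boxes.append([qi0, qi1, tj0, tj1])
    return [tuple(b) for b in boxes]


def align_duplex_seeded(
    q: SequenceRecord,
    t: SequenceRecord,
    matrix: PairingMatrix,
    min_score: int,
    seed_len: int = DEFAULT_SEED_LEN,
    window: int = DEFAULT_WINDOW,
    exhaustive_cells: int = DEFAULT_EXHAUSTIVE_CELLS,
    mode: str = "mRNA",
) -> List[DuplexAlignment]:
    """Seed-gated duplex search; deterministic, heuristic above the cutoff.

    Below ``exhaustive_cells`` DP cells the exhaustive search runs directly,
    so results coincide with :func:`align_duplex_exact` by construction.
    Above it, every alignment containing at least one perfectly pairing
    Watson-Crick run of ``seed_len`` is recovered via window-bounded
    exhaustive DP around seed clusters; alignments with no such run (possible
    in principle through long wobble chains) can be missed, which is the
    documented contract of seeding.
    """
    if seed_len < 4:
        raise ValueError("seed_len < 4 degenerates the seeding; use >= 4")
    if not q.seq or not t.seq:
        raise ValueError("empty sequence")
    if len(q.seq) * len(t.seq) <= exhaustive_cells:
        return align_duplex_exact(q, t, matrix, min_score, mode=mode)
    q_arr = encode(q.seq)
    tp_arr = _transform_target(t.seq)
    seeds = _find_seeds(q_arr, tp_arr, seed_len)
    if not seeds:
        return []
    sub = _substitution_table(matrix)
    candidates: List[Tuple[int, int, int, int, int, np.ndarray]] = []
    for qi0, qi1, tj0, tj1 in _cluster_windows(
        seeds, seed_len, window, len(q_arr), len(tp_arr)
    ):
        for score, i0, i1, j0, j1, ops in _iter_local_duplexes(
            q_arr[qi0:qi1], tp_arr[tj0:tj1], sub,
            matrix.gap_open, matrix.gap_extend, min_score,
        ):
            candidates.append((score, i0 + qi0, i1 + qi0, j0 + tj0, j1 + tj0, ops))
    # global greedy non-overlap selection across windows
    candidates.sort(key=lambda c: (-c[0], c[1], -c[4]))
    accepted: List[Tuple[int, int, int, int, int, np.ndarray]] = []
    for cand in candidates:
        _, i0, i1, j0, j1, _ = cand
        if all(
            i1 <= a[1] or a[2] <= i0 or j1 <= a[3] or a[4] <= j0
            for a in accepted
        ):
            accepted.append(cand)
    return _build_alignments(q, t, accepted, mode)


def search_transcriptome(
    lnc_set: Sequence[SequenceRecord],
    target_set: Sequence[SequenceRecord],
    matrix: PairingMatrix,
    min_score: int,
    mode: str = "mRNA",
    maf_path=None,
    **seeded_kwargs,
) -> List[DuplexAlignment]:
    """All-vs-all seeded search; stable (target_id, lnc_id, score desc) order."""
    if not lnc_set or not target_set:
        raise ValueError("lnc_set and target_set must be non-empty")
    lnc_ids = {r.id for r in lnc_set}
    shared = lnc_ids & {r.id for r in target_set}
    if shared:
        raise ValueError(f"id collision between lnc and target sets: {sorted(shared)}")
    hits: List[DuplexAlignment] = []
    for t in target_set:
        for q in lnc_set:
            hits.extend(
                align_duplex_seeded(q, t, matrix, min_score, mode=mode, **seeded_kwargs)
            )
    hits.sort(
        key=lambda a: (a.target_id, a.lnc_id, -a.score, a.lnc_interval, a.target_interval)
    )
    if maf_path is not None:
        write_maf(hits, maf_path)
    return hits
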