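"""Scoring economics for RNA:RNA duplex alignment.

A duplex column is scored by the strength of the base pair it forms:
G:C pairs score 4, A:T (A:U) 2 and the G:T (G:U) wobble 1; any other
combination is a mismatch at -6. Gaps use affine costs: a run of g gapped
columns on one molecule costs gap_open + g * gap_extend (-20 - 8g under the
defaults), i.e. the first gapped column of a run costs -28.

The module also provides the chance-alignment calibration: fit Gumbel
(extreme-value) statistics E(s) = K * m * n * exp(-lambda * s) to the maximal
local duplex scores of composition-preserving shuffled sequence pairs and
invert for the smallest integer score whose expected chance count over an
m x n search space falls below a target (one, by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .formats_io import VALID_BASES

BASES = "ACGTN"

_DEFAULT_PAIR_SCORES: Dict[FrozenSet[str], int] = {
    frozenset("GC"): 4,
    frozenset("AT"): 2,
    frozenset("GT"): 1,
}


@dataclass(frozen=True)
class PairingMatrix:
    """Pairing, mismatch and affine gap scores for duplex alignment.

    ``pair_scores`` maps unordered base pairs (as frozensets) to their bonus;
    anything absent, and anything involving N, scores ``mismatch``. Penalties
    are negative by convention.
    """

    pair_scores: Tuple[Tuple[FrozenSet[str], int], ...] = tuple(
        sorted(_DEFAULT_PAIR_SCORES.items(), key=lambda kv: sorted(kv[0]))
    )
    mismatch: int = -6
    gap_open: int = -20
    gap_extend: int = -8

    def __post_init__(self) -> None:
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")

    @property
    def pair_score_map(self) -> Dict[FrozenSet[str], int]:
        return dict(self.pair_scores)

    def min_positive_score(self) -> int:
        return min(v for _, v in self.pair_scores if v > 0)


def default_matrix() -> PairingMatrix:
    """The published matrix: G:C=4, A:T=2, G:T=1, mismatch -6, gaps -20/-8."""
    return PairingMatrix()


def pair_score(matrix: PairingMatrix, base_q: str, base_t: str) -> int:
    """Score of the duplex pair (base_q, base_t); symmetric in its arguments."""
    if base_q not in VALID_BASES or base_t not in VALID_BASES:
        raise ValueError(f"invalid base pair ({base_q!r}, {base_t!r})")
    if base_q == "N" or base_t == "N":
        return matrix.mismatch
    return matrix.pair_score_map.get(frozenset((base_q, base_t)), matrix.mismatch)


def alignment_score(matrix: PairingMatrix, columns: Sequence[Tuple[str, str]]) -> int:
    """Recompute an alignment score from its columns.

    Each pairing column contributes its pair/mismatch score; each maximal gap
    run of length g on one molecule contributes gap_open + g * gap_extend.
    A column gapped on both molecules is malformed.
    """
    score = 0
    gap_side: Optional[int] = None  # 0 = gap in query, 1 = gap in target
    for qc, tc in columns:
        if qc == "-" and tc == "-":
            raise ValueError("column gapped on both molecules")
        if qc == "-" or tc == "-":
            side = 0 if qc == "-" else 1
            if gap_side != side:
                score += matrix.gap_open
            score += matrix.gap_extend
            gap_side = side
        else:
            score += pair_score(matrix, qc, tc)
            gap_side = None
    return score


# ---------------------------------------------------------------------------
# Matrix (de)serialization: whitespace-delimited 5x5 table over A C G T N.
# Entry [x][y] is the duplex score of pairing base x with base y. Optional
# comment lines '# gap_open <int>' / '# gap_extend <int>' carry the gap terms.
# ---------------------------------------------------------------------------


def matrix_to_table(matrix: PairingMatrix) -> str:
    lines = [f"# gap_open {matrix.gap_open}", f"# gap_extend {matrix.gap_extend}"]
    lines.append("\t" + "\t".join(BASES))
    for x in BASES:
        row = [x]
        for y in BASES:
            row.append(str(pair_score(matrix, x, y)))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def matrix_from_table(text: str) -> PairingMatrix:
    gap_open, gap_extend = -20, -8
    rows: Dict[str, Dict[str, int]] = {}
    header: List[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if len(fields) == 2 and fields[0] in ("gap_open", "gap_extend"):
                if fields[0] == "gap_open":
                    gap_open = int(fields[1])
                else:
                    gap_extend = int(fields[1])
            continue
        fields = line.split()
        if not header:
            header = fields
            if header[0] in BASES and len(header) == len(BASES):
                pass
            else:
                header = fields[-len(BASES):]
            continue
        base, values = fields[0], fields[1:]
        rows[base] = {y: int(v) for y, v in zip(header, values)}
    if set(rows) != set(BASES):
        raise ValueError("matrix table must cover bases A C G T N")
    for x in BASES:
        for y in BASES:
            if rows[x][y] != rows[y][x]:
                raise ValueError(f"matrix table not symmetric at ({x},{y})")
    mismatch = rows["A"]["A"]
    pair_scores = {}
    for pair in (frozenset("GC"), frozenset("AT"), frozenset("GT")):
        x, y = sorted(pair)
        if rows[x][y] != mismatch:
            pair_scores[pair] = rows[x][y]
    return PairingMatrix(
        pair_scores=tuple(sorted(pair_scores.items(), key=lambda kv: sorted(kv[0]))),
        mismatch=mismatch,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


# ---------------------------------------------------------------------------
# Chance-alignment calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GumbelFit:
    """Extreme-value fit E(s) = K * m * n * exp(-lam * s) for chance scores."""

    lam: float
    K: float
    m: int
    n: int

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Gumbel parameters must be positive")

    def expected_alignments(self, score: float) -> float:
        return self.K * self.m * self.n * math.exp(-self.lam * score)

    def threshold_for(self, target: float, floor: int = 1) -> int:
        """Smallest integer s with expected chance count strictly below target."""
        if target <= 0:
            raise ValueError("target expected count must be positive")
        # E(s) < target  <=>  s > ln(K m n / target) / lam
        s = math.log(self.K * self.m * self.n / target) / self.lam
        return max(floor, math.floor(s) + 1)


def shuffle_preserving_composition(seq: str, rng: np.random.Generator) -> str:
    """Mononucleotide-composition-preserving shuffle."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    rng.shuffle(arr)
    return arr.tobytes().decode()


def random_sequence(
    length: int, rng: np.random.Generator, gc: float = 0.5
) -> str:
    """An i.i.d. random sequence with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _null_pair_iter(
    null_model: Union[None, Sequence[str], Sequence[Tuple[str, str]], dict],
    n_null_pairs: int,
    rng: np.random.Generator,
):
    """Yield (q, t) null sequence pairs under the requested null model.

    ``null_model`` may be: None (uniform i.i.d. 300-mers); a dict with keys
    'length' and optional 'gc'; a flat pool of sequences (sampled and
    shuffled); or a list of (q, t) pairs (each member shuffled).
    """
    if null_model is None:
        null_model = {"length": 300, "gc": 0.5}
    if isinstance(null_model, dict):
        length = int(null_model["length"])
        gc = float(null_model.get("gc", 0.5))
        for _ in range(n_null_pairs):
            yield random_sequence(length, rng, gc), random_sequence(length, rng, gc)
        return
    pool = list(null_model)
    if pool and isinstance(pool[0], tuple):
        for k in range(n_null_pairs):
            q, t = pool[k % len(pool)]
            yield (
                shuffle_preserving_composition(q, rng),
                shuffle_preserving_composition(t, rng),
            )
        return
    for _ in range(n_null_pairs):
        idx = rng.integers(0, len(pool), size=2)
        yield (
            shuffle_preserving_composition(pool[int(idx[0])], rng),
            shuffle_preserving_composition(pool[int(idx[1])], rng),
        )


def calibrate_threshold(
    matrix: PairingMatrix,
    m: int,
    n: int,
    target_expected_alignments: float = 1.0,
    null_model: Union[None, Sequence[str], Sequence[Tuple[str, str]], dict] = None,
    n_null_pairs: int = 200,
    seed: int = 0,
) -> Tuple[int, GumbelFit]:
    """Calibrate the duplex score threshold against a shuffled null.

    Collects the maximal local duplex score of ``n_null_pairs`` null sequence
    pairs, fits a Gumbel law to the maxima by maximum likelihood, converts the
    location/scale to Karlin-Altschul (lambda, K), and returns the smallest
    integer threshold whose expected chance-alignment count over an m x n
    search space is strictly below ``target_expected_alignments``, together
    with the fit. Deterministic for a given seed.
    """
    from .duplex_align import best_duplex_score  # local import: avoid cycle

    if m <= 0 or n <= 0:
        raise ValueError("search-space dimensions must be positive")
    if target_expected_alignments <= 0:
        raise ValueError("target expected count must be positive")
    rng = np.random.default_rng(seed)
    scores: List[float] = []
    log_areas: List[float] = []
    for q, t in _null_pair_iter(null_model, n_null_pairs, rng):
        scores.append(float(best_duplex_score(q, t, matrix)))
        log_areas.append(math.log(len(q)) + math.log(len(t)))
    if len(set(scores)) < 2:
        raise ValueError("degenerate null: all maximal scores identical")
    loc, scale = stats.gumbel_r.fit(np.asarray(scores))
    lam = 1.0 / scale
    area = math.exp(float(np.mean(log_areas)))
    K = math.exp(loc / scale) / area
    fit = GumbelFit(lam=lam, K=K, m=m, n=n)
    floor = matrix.min_positive_score()
    return fit.threshold_for(target_expected_alignments, floor=floor), fit


#: Default score thresholds used by the pipeline (calibrated at transcriptome
#: scale in the original study); mature-transcript and pre-mRNA search modes.
DEFAULT_THRESHOLD_MRNA = 107
DEFAULT_THRESHOLD_PREMRNA = 108
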