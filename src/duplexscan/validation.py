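"""Accuracy protocol: random-pair specificity and positive-set sensitivity.

Specificity is estimated by pairing randomly drawn lncRNAs and targets
one-to-one and asking how often the aligner reports any duplex at or above
the threshold (it should almost never, if the threshold is calibrated to
less than one chance alignment). Sensitivity is the recovered fraction of a
known-positive pair list.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple, Union

import numpy as np

from .duplex_align import align_duplex_seeded
from .formats_io import SequenceRecord
from .scoring import PairingMatrix


def specificity_test(
    pool_lnc: Sequence[SequenceRecord],
    pool_targets: Sequence[SequenceRecord],
    n_pairs: int,
    matrix: PairingMatrix,
    threshold: int,
    seed: int = 0,
) -> Tuple[float, List[Tuple[str, str, int]]]:
    """Fraction of random one-to-one pairings with a reported duplex.

    Samples ``n_pairs`` members from each pool without replacement (seeded),
    pairs them up, and runs the seeded aligner on each pair. Returns
    (hit_fraction, hits) where hits holds (lnc_id, target_id, best_score);
    specificity = 1 - hit_fraction.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if len(pool_lnc) < n_pairs or len(pool_targets) < n_pairs:
        raise ValueError(
            f"pools too small for {n_pairs} pairs "
            f"({len(pool_lnc)} lncRNAs, {len(pool_targets)} targets)"
        )
    rng = np.random.default_rng(seed)
    lnc_idx = rng.choice(len(pool_lnc), size=n_pairs, replace=False)
    tgt_idx = rng.choice(len(pool_targets), size=n_pairs, replace=False)
    hits: List[Tuple[str, str, int]] = []
    for li, ti in zip(lnc_idx, tgt_idx):
        q, t = pool_lnc[int(li)], pool_targets[int(ti)]
        alns = align_duplex_seeded(q, t, matrix, threshold)
        if alns:
            hits.append((q.id, t.id, alns[0].score))
    return len(hits) / n_pairs, hits


def sensitivity_test(
    positive_pairs: Sequence[Tuple[Union[str, SequenceRecord], Union[str, SequenceRecord]]],
    matrix: PairingMatrix,
    threshold: int,
) -> float:
    """Fraction of known-positive pairs with a duplex at or above threshold."""
    if not positive_pairs:
        raise ValueError("positive pair list is empty")
    recovered = 0
    for k, (lnc, tgt) in enumerate(positive_pairs):
        q = lnc if isinstance(lnc, SequenceRecord) else SequenceRecord(f"lnc{k}", lnc)
        t = tgt if isinstance(tgt, SequenceRecord) else SequenceRecord(f"tgt{k}", tgt)
        if align_duplex_seeded(q, t, matrix, threshold):
            recovered += 1
    return recovered / len(positive_pairs)
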