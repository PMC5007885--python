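"""Recovery metrics against the synthetic ground truth.

These functions score each pipeline stage against a
:class:`~agoblocks.simulate.SyntheticTruth`: how many planted blocks the
discovery stage recovered, how many proteins got their exact planted block
string back from scanning, whether each clade's consensus and the
clade-specific sets match the realized (seed-dependent) truth, and how often
N-terminal repeat copy counts are counted exactly.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .discovery import DiscoveredMotif
from .models import Architecture, BlockModel
from .simulate import SyntheticTruth


def consensus_distance(a: str, b: str) -> int:
    """Best ungapped Hamming distance of the shorter string slid along the
    longer (full containment of the shorter)."""
    if len(a) > len(b):
        a, b = b, a
    return min(
        sum(x != y for x, y in zip(a, b[off : off + len(a)]))
        for off in range(len(b) - len(a) + 1)
    )


def motif_matches_block(
    motif_consensus: str,
    planted_consensus: str,
    mismatch_fraction: float = 0.1,
    min_coverage: float = 0.6,
) -> bool:
    """Does a discovered consensus recover a planted block?

    The shorter of the two strings must fit inside the longer with at most
    ceil(len(shorter) * mismatch_fraction) mismatches, and must cover at
    least ``min_coverage`` of the planted width (so a short spurious motif
    cannot claim a long block).
    """
    short = min(len(motif_consensus), len(planted_consensus))
    if short < min_coverage * len(planted_consensus):
        return False
    import math

    budget = math.ceil(short * mismatch_fraction)
    return consensus_distance(motif_consensus, planted_consensus) <= budget


def discovery_recovery(
    motifs: Sequence[DiscoveredMotif],
    planted_models: Mapping[int, BlockModel],
    target_blocks: Optional[Sequence[int]] = None,
) -> tuple[float, dict[int, bool]]:
    """Fraction of target planted blocks matched by >= 1 discovered motif.

    ``target_blocks`` defaults to every planted model; callers normally pass
    the high-presence architecture blocks (excluding the N-terminal repeat
    block, which is recovered by scanning rather than discovery, and rare
    clade-specific extras below the detection floor of a ZOOPS search).
    """
    targets = list(target_blocks) if target_blocks is not None else sorted(planted_models)
    found: dict[int, bool] = {}
    for b in targets:
        planted = planted_models[b].consensus
        found[b] = any(motif_matches_block(m.consensus, planted) for m in motifs)
    rate = sum(found.values()) / len(found) if found else 0.0
    return rate, found


def architecture_match_rate(
    architectures: Sequence[Architecture], truth: SyntheticTruth
) -> float:
    """Fraction of proteins whose scanned block string equals the planted one."""
    if not architectures:
        return 0.0
    good = sum(
        1
        for a in architectures
        if a.block_string == truth.planted_block_string(a.protein_id)
    )
    return good / len(architectures)


def consensus_order_matches(
    recovered: Sequence[int], truth: SyntheticTruth, clade_id: str, threshold: float = 0.90
) -> bool:
    """Does a recovered clade consensus equal the realized planted consensus?

    The reference is the deduplicated planted architecture restricted to
    blocks whose realized presence fraction reaches the threshold (presence
    is sampled, so a planted block can legitimately fall below 90% for a
    given seed).
    """
    return list(recovered) == truth.realized_consensus(clade_id, threshold)


def specific_sets_match(
    recovered: Mapping[str, set], truth: SyntheticTruth
) -> bool:
    expected = truth.realized_specific_blocks()
    return {c: set(v) for c, v in recovered.items()} == expected


def repeat_count_accuracy(
    counts: Mapping[str, int], truth: SyntheticTruth
) -> float:
    """Fraction of proteins whose counted N-terminal repeat copies equal the
    planted copy number."""
    if not counts:
        return 0.0
    good = sum(1 for pid, k in counts.items() if truth.repeat_counts.get(pid, 0) == k)
    return good / len(counts)
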