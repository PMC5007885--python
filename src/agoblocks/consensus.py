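"""The clade consensus calculus over block presence/absence.

Given per-protein block architectures and a protein -> clade mapping, this
module computes:

* the **presence matrix** (protein x block booleans; multiple copies of a
  block collapse to one cell),
* each clade's **block consensus sequence** — the blocks present in at least
  a threshold fraction (default 90%, compared with >=, so 9/10 passes) of
  the clade's members, ordered by the median rank of the block among the
  member architectures that contain it (ties: mean start position, then
  block id),
* **clade-specific blocks** — blocks present in >= 1 member of exactly one
  clade (raw presence, not the consensus),
* the **k-of-n group consensus** (the "Viridiplantae consensus" construction:
  blocks present in at least 2 of the 4 clade consensuses), and
* the segmentation of an ordered consensus into named **domain series**
  (maximal runs of one domain class, matched against a catalog).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import io as agio
from .models import Architecture, CladeConsensus, DomainSeries

#: Blocks of the two novel conserved series flanking the canonical domains.
DOMAIN_A_BLOCKS = frozenset({13, 14, 17, 20, 24, 28, 34, 35, 41})
DOMAIN_B_BLOCKS = frozenset({9, 12, 19, 30, 32, 36, 44, 49})


@dataclass
class PresenceMatrix:
    """Boolean protein x block matrix plus the protein -> clade mapping."""

    presence: pd.DataFrame  # index: protein_id, columns: block_id (int)
    groups: dict[str, str]

    @property
    def clades(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def members(self, clade: str) -> list[str]:
        return [pid for pid in self.presence.index if self.groups[pid] == clade]


def build_presence_matrix(
    architectures: Sequence[Architecture],
    groups: Mapping[str, str],
    block_ids: Optional[Sequence[int]] = None,
) -> PresenceMatrix:
    """Presence matrix from architectures; every protein must have a group."""
    missing = [a.protein_id for a in architectures if a.protein_id not in groups]
    if missing:
        raise ValueError(f"protein(s) without group label: {missing[:5]}")
    if block_ids is None:
        block_ids = sorted({o.block_id for a in architectures for o in a.occurrences})
    cols = sorted(block_ids)
    index = [a.protein_id for a in architectures]
    df = pd.DataFrame(False, index=index, columns=cols, dtype=bool)
    for arch in architectures:
        for occ in arch.occurrences:
            if occ.block_id in df.columns:
                df.loc[arch.protein_id, occ.block_id] = True
    return PresenceMatrix(presence=df, groups={a.protein_id: groups[a.protein_id] for a in architectures})


def clade_consensus(
    matrix: PresenceMatrix,
    clade: str,
    architectures: Sequence[Architecture],
    threshold: float = 0.90,
) -> CladeConsensus:
    """One clade's ordered >= threshold consensus block sequence."""
    members = matrix.members(clade)
    if not members:
        raise ValueError(f"clade {clade!r} has no members")
    arch_by_id = {a.protein_id: a for a in architectures}
    sub = matrix.presence.loc[members]
    fractions = sub.mean(axis=0)
    included = [int(b) for b in fractions.index if fractions[b] >= threshold]

    def sort_key(b: int):
        ranks, starts = [], []
        for pid in members:
            arch = arch_by_id.get(pid)
            if arch is None:
                continue
            string = arch.block_string
            if b in string:
                ranks.append(string.index(b) + 1)
                starts.append(
                    min(o.start for o in arch.occurrences if o.block_id == b)
                )
        if not ranks:  # consensus block must appear somewhere, but be safe
            return (float("inf"), float("inf"), b)
        return (statistics.median(ranks), statistics.fmean(starts), b)

    ordered = sorted(included, key=sort_key)
    return CladeConsensus(
        clade_id=clade,
        member_count=len(members),
        threshold=threshold,
        ordered_blocks=ordered,
    )


def clade_specific_blocks(matrix: PresenceMatrix) -> dict[str, set[int]]:
    """Blocks present in >= 1 member of exactly one clade, per clade."""
    clades = matrix.clades
    if len(clades) < 2:
        raise ValueError("clade-specificity needs >= 2 clades")
    out: dict[str, set[int]] = {c: set() for c in clades}
    by_clade = {
        c: matrix.presence.loc[matrix.members(c)].any(axis=0) for c in clades
    }
    for b in matrix.presence.columns:
        present_in = [c for c in clades if bool(by_clade[c][b])]
        if len(present_in) == 1:
            out[present_in[0]].add(int(b))
    return out


def group_consensus(
    clade_consensuses: Sequence[Union[CladeConsensus, set, frozenset]],
    k: int = 2,
) -> set[int]:
    """Blocks appearing in >= k of the supplied clade consensus block sets."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(clade_consensuses) < k:
        raise ValueError(f"need >= {k} clade consensuses, got {len(clade_consensuses)}")
    sets = [
        set(c.ordered_blocks) if isinstance(c, CladeConsensus) else set(c)
        for c in clade_consensuses
    ]
    all_blocks = set().union(*sets)
    return {b for b in all_blocks if sum(b in s for s in sets) >= k}


def default_block_class_map() -> dict[int, str]:
    """Block -> domain class from the packaged block table plus the A/B series."""
    out: dict[int, str] = {}
    for m in agio.load_packaged_blocks():
        if m.domain_tag != "NONE":
            out[m.block_id] = m.domain_tag
    for b in DOMAIN_A_BLOCKS:
        out.setdefault(b, "A")
    for b in DOMAIN_B_BLOCKS:
        out.setdefault(b, "B")
    return out


def name_domain_series(
    consensus: Sequence[int],
    block_class_map: Optional[Mapping[int, str]] = None,
    series_catalog: Optional[Sequence[DomainSeries]] = None,
) -> list[DomainSeries]:
    """Segment an ordered consensus into named domain series.

    The consensus is cut into maximal runs of a single domain class
    (unmapped blocks get class "unassigned"); each run is matched against
    the catalog by exact ordered block identity, falling back to a
    "<class>-new" series carrying the run itself.
    """
    if block_class_map is None:
        block_class_map = default_block_class_map()
    if series_catalog is None:
        series_catalog = agio.load_series_catalog()
    by_blocks = {s.blocks: s for s in series_catalog}
    out: list[DomainSeries] = []
    run: list[int] = []
    run_class: Optional[str] = None

    def flush() -> None:
        if not run:
            return
        key = tuple(run)
        if key in by_blocks:
            out.append(by_blocks[key])
        else:
            out.append(DomainSeries(name=f"{run_class}-new", blocks=key, domain_class=run_class))

    for b in consensus:
        cls = block_class_map.get(b, "unassigned")
        if cls != run_class and run:
            flush()
            run = []
        run_class = cls
        run.append(b)
    flush()
    return out
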