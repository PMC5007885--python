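"""Cross-kingdom posttranslational-modification signatures in AGO proteins.

Two animal AGO/PIWI regulatory motifs have plant counterparts within the
conserved block set:

* the **x-P-G prolyl-hydroxylation site** (any residue, proline, glycine;
  the proline of human AGO2 is hydroxylated by a collagen prolyl-4-
  hydroxylase), associated with block 8 — the association is implemented as
  a proximity filter around block-8 occurrences, because the printed block-8
  consensus itself ends just before the glycine;
* the **glycine/arginine-rich methylation region** (block 43), present in
  0-8 consecutive copies at the N-terminus; its arginines are the targets
  of symmetric methylation in PIWI-clade proteins such as AUBERGINE.

A third check reads the candidate catalytic residues of the PIWI-domain
DDH/DDD triad from blocks 5, 3 and 2 of a protein's architecture.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Optional

from . import io as agio
from .models import Architecture, BlockModel, MotifHit, ProteinRecord
from .scanning import count_block_copies, scan_protein

#: Per-site p-value threshold for repeat counting.  The G/R repeat block is
#: low-complexity, so glycine-rich stretches of unrelated blocks reach the
#: generic scanning threshold by composition alone; exact per-copy counting
#: needs the stringent end of the scanning settings.
GR_P_THRESHOLD = 1e-6

XPG_PATTERN = re.compile(r"(?=(.PG))")
#: Blocks carrying the catalytic triad, in triad order (D, D, H/D).
CATALYTIC_BLOCKS = (5, 3, 2)


def _context(sequence: str, position: int, pad: int = 5) -> str:
    """±pad residues around a 1-based position, clipped at the ends."""
    lo = max(0, position - 1 - pad)
    return sequence[lo : position + pad]


def find_xpg_sites(
    protein: ProteinRecord,
    architecture: Optional[Architecture] = None,
    within_block: Optional[int] = 8,
    margin: int = 5,
) -> list[MotifHit]:
    """All x-P-G matches, reported at the proline position (1-based).

    When ``within_block`` is set and an architecture is supplied, only
    prolines inside (or within ``margin`` residues of) an occurrence of that
    block are reported; otherwise the whole protein is scanned.
    """
    hits = []
    for m in XPG_PATTERN.finditer(protein.sequence):
        proline = m.start() + 2  # 1-based position of the P in x-P-G
        hits.append(
            MotifHit(
                protein_id=protein.id,
                motif_name="x-P-G",
                position=proline,
                context=_context(protein.sequence, proline),
            )
        )
    if architecture is None or within_block is None:
        return hits
    windows = [
        (o.start - margin, o.end + margin)
        for o in architecture.occurrences
        if o.block_id == within_block
    ]
    return [h for h in hits if any(lo <= h.position <= hi for lo, hi in windows)]


def count_gr_repeat_copies(
    protein: ProteinRecord,
    repeat_model: Optional[BlockModel] = None,
    n_terminal_fraction: float = 0.25,
    p_threshold: float = GR_P_THRESHOLD,
) -> int:
    """Number of non-overlapping repeat-block hits starting in the first
    ``ceil(n_terminal_fraction * L)`` residues (the N-terminal region)."""
    if repeat_model is None:
        repeat_model = _default_repeat_model()
    arch = scan_protein([repeat_model], protein, p_threshold=p_threshold)
    region_end = math.ceil(n_terminal_fraction * len(protein))
    return count_block_copies(arch, repeat_model.block_id, region_end=region_end)


def gr_arginine_sites(
    protein: ProteinRecord,
    repeat_model: Optional[BlockModel] = None,
    n_terminal_fraction: float = 0.25,
    p_threshold: float = GR_P_THRESHOLD,
) -> list[MotifHit]:
    """One hit per arginine inside an accepted N-terminal repeat copy."""
    if repeat_model is None:
        repeat_model = _default_repeat_model()
    arch = scan_protein([repeat_model], protein, p_threshold=p_threshold)
    region_end = math.ceil(n_terminal_fraction * len(protein))
    hits = []
    for occ in arch.occurrences:
        if occ.start > region_end:
            continue
        for pos in range(occ.start, occ.end + 1):
            if protein.sequence[pos - 1] == "R":
                hits.append(
                    MotifHit(
                        protein_id=protein.id,
                        motif_name="GR-methylation",
                        position=pos,
                        context=_context(protein.sequence, pos),
                    )
                )
    return hits


def _default_repeat_model(match_prob: float = 0.9) -> BlockModel:
    models = {m.block_id: m for m in agio.load_packaged_blocks(match_prob=match_prob)}
    return models[43]


@dataclass
class CatalyticReport:
    """Residues read at the configured catalytic offsets of blocks 5/3/2."""

    protein_id: str
    residues: dict[int, Optional[str]]  # block_id -> residue or None (absent)
    classification: str  # "DDH" | "DDD" | "other" | "incomplete"


def default_catalytic_offsets() -> dict[int, int]:
    """1-based within-block offsets of the candidate catalytic residues,
    derived from the packaged consensus strings: the first aspartate of
    blocks 5 and 3 and the first histidine of block 2."""
    models = {m.block_id: m for m in agio.load_packaged_blocks()}
    return {
        5: models[5].consensus.index("D") + 1,
        3: models[3].consensus.index("D") + 1,
        2: models[2].consensus.index("H") + 1,
    }


def check_catalytic_residues(
    protein: ProteinRecord,
    architecture: Architecture,
    offsets_config: Optional[Mapping[int, int]] = None,
) -> CatalyticReport:
    """Read the DDH/DDD triad candidates from a protein's architecture.

    For each of blocks 5, 3 and 2 present in the architecture, reports the
    residue at the configured within-block offset (first occurrence of the
    block is used).  Classification is "DDH" or "DDD" when the triad reads
    exactly so, "incomplete" when any block is missing, "other" otherwise.
    """
    offsets = dict(offsets_config) if offsets_config else default_catalytic_offsets()
    residues: dict[int, Optional[str]] = {}
    for block_id in CATALYTIC_BLOCKS:
        occ = next(
            (o for o in architecture.occurrences if o.block_id == block_id), None
        )
        if occ is None:
            residues[block_id] = None
            continue
        off = offsets[block_id]
        if off > occ.width:
            raise ValueError(
                f"block {block_id}: offset {off} beyond block width {occ.width}"
            )
        residues[block_id] = protein.sequence[occ.start + off - 2]
    triad = tuple(residues[b] for b in CATALYTIC_BLOCKS)
    if None in triad:
        classification = "incomplete"
    elif triad == ("D", "D", "H"):
        classification = "DDH"
    elif triad == ("D", "D", "D"):
        classification = "DDD"
    else:
        classification = "other"
    return CatalyticReport(
        protein_id=protein.id, residues=residues, classification=classification
    )
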