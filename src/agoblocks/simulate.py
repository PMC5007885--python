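"""Synthetic clade-structured AGO-like protein families with planted blocks.

The generator emulates the structure of the plant ARGONAUTE family as used
throughout this package: four clades (default sizes 44, 55, 28 and 58, i.e.
185 proteins), each with a fixed ordered architecture of conserved blocks,
per-block presence probabilities near the 90% consensus boundary,
substitution noise inside blocks, i.i.d. background spacers between blocks,
and an optional N-terminal glycine/arginine repeat block planted in 0-8
consecutive copies.  Every planted coordinate, clade label, repeat count and
corruption is recorded in a :class:`SyntheticTruth` so downstream stages can
be scored against ground truth.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from Bio.Data import CodonTable

from . import io as agio
from .models import (
    AMINO_ACIDS,
    BlockModel,
    CodingSequence,
    DomainAnnotation,
    ProteinRecord,
    uniform_background,
)

#: The study frame the generator emulates: 206 genes entered the phylogeny,
#: 21 (bryophyte/gymnosperm/incomplete) were excluded before block analysis.
PHYLOGENY_SEQUENCE_COUNT = 206
EXCLUDED_SEQUENCE_COUNT = 21

#: Default per-block presence probability (just above the 90% consensus rule).
DEFAULT_PRESENCE = 0.95
#: Default within-block conservation (consensus-residue probability).
DEFAULT_CONSERVATION = 0.95
DEFAULT_SPACER = (5, 15)
REPEAT_MAX_COPIES = 8


@dataclass
class CladeSpec:
    """One clade's generative recipe.

    ``architecture`` is the clade's true ordered block list; ``presence_prob``
    is either a single probability applied to every block or a per-block
    mapping.  ``repeat_block`` (if set) is planted in 0..``repeat_max``
    consecutive copies at the N-terminus.
    """

    clade_id: str
    n_members: int
    architecture: list[int]
    presence_prob: Union[float, Mapping[int, float]] = DEFAULT_PRESENCE
    repeat_block: Optional[int] = None
    repeat_max: int = REPEAT_MAX_COPIES
    spacer_range: tuple[int, int] = DEFAULT_SPACER

    def __post_init__(self) -> None:
        if not self.architecture:
            raise ValueError(f"clade {self.clade_id}: architecture must be non-empty")
        if self.n_members < 1:
            raise ValueError(f"clade {self.clade_id}: n_members must be positive")
        lo, hi = self.spacer_range
        if lo < 0 or hi < lo:
            raise ValueError(f"clade {self.clade_id}: invalid spacer range {lo}..{hi}")
        probs = self._prob_list()
        if any(not (0.0 < p <= 1.0) for p in probs):
            raise ValueError(f"clade {self.clade_id}: presence probabilities must be in (0,1]")

    def _prob_list(self) -> list[float]:
        if isinstance(self.presence_prob, Mapping):
            return [self.presence_prob.get(b, DEFAULT_PRESENCE) for b in self.architecture]
        return [float(self.presence_prob)] * len(self.architecture)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated family: the recovery oracle.

    ``occurrences`` maps protein id to the planted ``(block_id, start)`` list
    (1-based starts, in N-to-C order, repeat copies included);
    ``should_be_discarded`` collects proteins whose PAZ or PIWI annotation is
    missing (naturally or by corruption) and that the canonical-domain filter
    must therefore reject.
    """

    models: dict[int, BlockModel]
    occurrences: dict[str, list[tuple[int, int]]]
    clades: dict[str, str]
    repeat_counts: dict[str, int] = field(default_factory=dict)
    clade_architectures: dict[str, list[int]] = field(default_factory=dict)
    should_be_discarded: set[str] = field(default_factory=set)

    def members(self, clade_id: str) -> list[str]:
        return [pid for pid, c in self.clades.items() if c == clade_id]

    def planted_block_string(self, protein_id: str) -> list[int]:
        occs = sorted(self.occurrences[protein_id], key=lambda t: t[1])
        return [b for b, _ in occs]

    def presence_fraction(self, clade_id: str, block_id: int) -> float:
        members = self.members(clade_id)
        present = sum(
            1
            for pid in members
            if any(b == block_id for b, _ in self.occurrences[pid])
        )
        return present / len(members)

    def realized_consensus(self, clade_id: str, threshold: float = 0.90) -> list[int]:
        """Blocks whose realized presence fraction is >= threshold, ordered by
        the median rank of their first planted occurrence (the same ordering
        rule the consensus stage uses)."""
        members = self.members(clade_id)
        blocks = {b for pid in members for b, _ in self.occurrences[pid]}
        included = [
            b for b in blocks if self.presence_fraction(clade_id, b) >= threshold
        ]

        def sort_key(b: int):
            ranks, starts = [], []
            for pid in members:
                string = self.planted_block_string(pid)
                if b in string:
                    ranks.append(string.index(b) + 1)
                    starts.append(
                        min(s for bb, s in self.occurrences[pid] if bb == b)
                    )
            return (statistics.median(ranks), statistics.fmean(starts), b)

        return sorted(included, key=sort_key)

    def realized_specific_blocks(self) -> dict[str, set[int]]:
        """Blocks present in >=1 member of exactly one clade, per clade."""
        clade_ids = sorted(set(self.clades.values()))
        seen: dict[int, set[str]] = {}
        for pid, occs in self.occurrences.items():
            for b, _ in occs:
                seen.setdefault(b, set()).add(self.clades[pid])
        out = {c: set() for c in clade_ids}
        for b, clades in seen.items():
            if len(clades) == 1:
                out[next(iter(clades))].add(b)
        return out

    def to_json(self, path) -> None:
        payload = {
            "occurrences": {k: list(map(list, v)) for k, v in self.occurrences.items()},
            "clades": self.clades,
            "repeat_counts": self.repeat_counts,
            "clade_architectures": self.clade_architectures,
            "should_be_discarded": sorted(self.should_be_discarded),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Model generation
# ---------------------------------------------------------------------------

def generate_block_models(
    n_blocks: int,
    width_min: int = 8,
    width_max: int = 50,
    conservation: float = DEFAULT_CONSERVATION,
    seed: int = 0,
) -> list[BlockModel]:
    """Random block models: widths uniform in [width_min, width_max], each
    column putting ``conservation`` on one uniformly drawn residue."""
    if not (1 <= width_min <= width_max):
        raise ValueError("require 1 <= width_min <= width_max")
    if not (1.0 / 20.0 < conservation <= 1.0):
        raise ValueError("conservation must exceed 1/20 (consensus undefined below)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    models = []
    for i in range(n_blocks):
        w = int(rng.integers(width_min, width_max + 1))
        consensus = "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=w))
        models.append(
            BlockModel.from_consensus(i + 1, consensus, match_prob=conservation)
        )
    return models


def table_models(conservation: float = DEFAULT_CONSERVATION) -> dict[int, BlockModel]:
    """The packaged 50 plant AGO blocks as generative models."""
    return {m.block_id: m for m in agio.load_packaged_blocks(match_prob=conservation)}


def sample_instance(model: BlockModel, rng: np.random.Generator) -> str:
    """Draw one block instance, residue by residue, from the model columns."""
    cum = model.matrix.cumsum(axis=1)
    u = rng.random(model.width)
    # ">=" keeps the degenerate conservation=1.0 case exact even when u == 0
    idx = (u[:, None] >= cum).sum(axis=1)
    return "".join(AMINO_ACIDS[i] for i in idx)


# ---------------------------------------------------------------------------
# Default study configuration (four plant AGO clades)
# ---------------------------------------------------------------------------

#: Positions (clade, insert-after-block-index) of rarely present clade-specific
#: blocks, expressed as (block_id, presence_prob, index in architecture).
_SPECIFIC_PRESENCE = 0.30


def default_clade_specs(
    scale: float = 1.0,
    presence: float = DEFAULT_PRESENCE,
    spacer_range: tuple[int, int] = DEFAULT_SPACER,
) -> list[CladeSpec]:
    """The four plant AGO clades with their consensus architectures.

    Architectures come from the packaged clade/series catalog; the rarely
    present clade-specific blocks (e.g. 45/48 for AGO2/3/7) are inserted at
    plausible N/C-terminal or intra-domain positions with presence 0.30, and
    the G/R repeat block 43 is configured for the three clades that carry it.
    ``scale`` shrinks member counts proportionally (minimum 2 per clade).
    """
    table = agio.load_clade_table()
    archs = agio.clade_architectures(table)
    # Insertion plan for sub-consensus blocks: block -> position within the
    # clade architecture (index before which to insert), chosen to mimic the
    # described N-terminal, PAZ-adjacent, PIWI-adjacent or C-terminal placement.
    extras: dict[str, list[tuple[int, int]]] = {
        # 45 N-terminal (near block 13/35 region), 48 C-terminal
        "AGO2/3/7": [(45, 0), (48, 10**6)],
        # 37 adjacent to the PAZ run, 42 inside the PIWI run, 46/50 C-terminal,
        # 38 C-terminal (planted at 0.5 presence below, handled separately)
        "AGO4/6/8/9": [(37, 13), (42, 26), (46, 10**6), (50, 10**6)],
        "AGO5": [],
        "AGO1/10": [],
    }
    specs = []
    for _, row in table.iterrows():
        clade = row["clade"]
        arch = list(archs[clade])
        probs: dict[int, float] = {b: presence for b in arch}
        for block_id, pos in extras.get(clade, []):
            pos = min(pos, len(arch))
            arch.insert(pos, block_id)
            probs[block_id] = _SPECIFIC_PRESENCE
        if clade == "AGO4/6/8/9":
            arch.append(38)
            probs[38] = 0.5
        n = max(2, round(row["n_members"] * scale))
        specs.append(
            CladeSpec(
                clade_id=clade,
                n_members=n,
                architecture=arch,
                presence_prob=probs,
                repeat_block=row["repeat_block"],
                spacer_range=spacer_range,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------

def _sanitize(label: str) -> str:
    return label.replace("/", "-")


def generate_family(
    clade_specs: Sequence[CladeSpec],
    models: Mapping[int, BlockModel],
    seed: int = 0,
    background: Optional[np.ndarray] = None,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate one clade-structured protein family plus its ground truth.

    Per member: block presence is sampled independently per architecture
    entry, present blocks are instantiated from their model matrix and joined
    in architecture order with i.i.d.-background spacers; repeat copies are
    prepended consecutively at the N-terminus.  Deterministic given ``seed``.
    """
    if isinstance(models, Sequence):
        models = {m.block_id: m for m in models}
    for spec in clade_specs:
        wanted = set(spec.architecture)
        if spec.repeat_block is not None:
            wanted.add(spec.repeat_block)
        unknown = wanted - set(models)
        if unknown:
            raise ValueError(
                f"clade {spec.clade_id}: no model for block(s) {sorted(unknown)}"
            )
    bg = uniform_background() if background is None else np.asarray(background, float)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    records: list[ProteinRecord] = []
    truth = SyntheticTruth(models=dict(models), occurrences={}, clades={})
    for spec in clade_specs:
        truth.clade_architectures[spec.clade_id] = list(spec.architecture)
        probs = spec._prob_list()
        lo, hi = spec.spacer_range
        for i in range(spec.n_members):
            pid = f"{_sanitize(spec.clade_id)}_{i:03d}"
            parts: list[str] = []
            occs: list[tuple[int, int]] = []
            pos = 0  # 0-based cursor

            def spacer() -> None:
                nonlocal pos
                n = int(rng.integers(lo, hi + 1))
                if n:
                    parts.append(
                        "".join(
                            AMINO_ACIDS[j]
                            for j in rng.choice(20, size=n, p=bg)
                        )
                    )
                    pos += n

            k = 0
            if spec.repeat_block is not None:
                k = int(rng.integers(0, spec.repeat_max + 1))
                for _ in range(k):
                    inst = sample_instance(models[spec.repeat_block], rng)
                    occs.append((spec.repeat_block, pos + 1))
                    parts.append(inst)
                    pos += len(inst)
            truth.repeat_counts[pid] = k
            for block_id, p in zip(spec.architecture, probs):
                present = rng.random() < p
                if present:
                    spacer()
                    inst = sample_instance(models[block_id], rng)
                    occs.append((block_id, pos + 1))
                    parts.append(inst)
                    pos += len(inst)
            spacer()
            seq = "".join(parts)
            if not seq:  # every block absent and all spacers empty
                seq = AMINO_ACIDS[int(rng.integers(0, 20))]
            records.append(
                ProteinRecord(id=pid, sequence=seq, group=spec.clade_id)
            )
            truth.occurrences[pid] = occs
            truth.clades[pid] = spec.clade_id
    return records, truth


# ---------------------------------------------------------------------------
# Coding sequences and domain annotations
# ---------------------------------------------------------------------------

def _codon_choices() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


def generate_coding_and_annotations(
    proteins: Sequence[ProteinRecord],
    truth: SyntheticTruth,
    corruption_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[CodingSequence], list[DomainAnnotation]]:
    """Back-translate proteins and emit Pfam-style domain annotations.

    Codons are drawn uniformly among synonymous choices ('X' becomes NNN).
    For each of DUF1785/PAZ/PIWI the annotated span runs from the first to
    the last planted block carrying that domain tag.  With probability
    ``corruption_rate`` one of a protein's PAZ/PIWI annotations is deleted
    and the protein is flagged in ``truth.should_be_discarded``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    codons = _codon_choices()
    cds_list: list[CodingSequence] = []
    annotations: list[DomainAnnotation] = []
    for rec in proteins:
        nts = []
        for aa in rec.sequence:
            if aa == "X":
                nts.append("NNN")
            else:
                opts = codons[aa]
                nts.append(opts[int(rng.integers(0, len(opts)))])
        cds_list.append(CodingSequence(id=rec.id, nucleotides="".join(nts)))

        spans: dict[str, tuple[int, int]] = {}
        for block_id, start in truth.occurrences.get(rec.id, []):
            tag = truth.models[block_id].domain_tag
            if tag in ("DUF1785", "PAZ", "PIWI"):
                end = start + truth.models[block_id].width - 1
                if tag in spans:
                    spans[tag] = (min(spans[tag][0], start), max(spans[tag][1], end))
                else:
                    spans[tag] = (start, end)
        corrupt = rng.random() < corruption_rate
        drop: Optional[str] = None
        if corrupt:
            candidates = [d for d in ("PAZ", "PIWI") if d in spans]
            if candidates:
                drop = candidates[int(rng.integers(0, len(candidates)))]
        for tag in ("DUF1785", "PAZ", "PIWI"):
            if tag in spans and tag != drop:
                s, e = spans[tag]
                annotations.append(
                    DomainAnnotation(protein_id=rec.id, domain=tag, start=s, end=e)
                )
        emitted = {a.domain for a in annotations if a.protein_id == rec.id}
        if "PAZ" not in emitted or "PIWI" not in emitted:
            truth.should_be_discarded.add(rec.id)
    return cds_list, annotations
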