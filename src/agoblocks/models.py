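"""Core domain types for conserved-block analysis of ARGONAUTE proteins.

The unit of analysis is the *block*: a short conserved amino-acid sequence
(8-50 residues) shared across members of a protein family.  A block is
represented as a position probability matrix over the 20 standard residues
(:class:`BlockModel`); a scored, positioned match of a block on a protein is
a :class:`BlockOccurrence`; the ordered list of occurrences along one protein
is its :class:`Architecture` (the protein's "block string").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: The 20 standard amino acids, alphabetically; index 20 is the mask/unknown
#: residue 'X', which always scores as background.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
X_INDEX = 20
ALPHABET = AMINO_ACIDS + "X"

#: Residues outside the standard 20 that are collapsed to 'X' on input.
NONSTANDARD = set("BZJUO*")

DOMAIN_NAMES = ("DUF1785", "PAZ", "PIWI")
DOMAIN_TAGS = ("PIWI", "PAZ", "DUF1785", "NONE")

_ENCODE = np.full(128, -1, dtype=np.int8)
for _a, _i in AA_INDEX.items():
    _ENCODE[ord(_a)] = _i
_ENCODE[ord("X")] = X_INDEX


def encode(sequence: str) -> np.ndarray:
    """Encode an amino-acid string to int8 indices (0-19 residues, 20 = X)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    enc = _ENCODE[arr]
    if (enc < 0).any():
        bad = sequence[int(np.argmax(enc < 0))]
        raise ValueError(f"sequence contains unexpected character {bad!r}")
    return enc


def decode(indices: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in indices)


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


class AgoblocksError(Exception):
    """Base class for errors raised by this package."""


@dataclass
class ProteinRecord:
    """One protein: unique id, amino-acid sequence over the 21-letter alphabet."""

    id: str
    sequence: str
    species: Optional[str] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")
        encode(self.sequence)  # validates the alphabet

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CodingSequence:
    """Nucleotide coding sequence paired (by id) with a protein record."""

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        if set(self.nucleotides) - set("ACGTN"):
            bad = sorted(set(self.nucleotides) - set("ACGTN"))
            raise ValueError(f"CDS {self.id!r}: non-nucleotide characters {bad}")

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class DomainAnnotation:
    """A named domain span on a protein, 1-based inclusive coordinates."""

    protein_id: str
    domain: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_NAMES + ("OTHER",):
            raise ValueError(f"unknown domain {self.domain!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.domain}: invalid span {self.start}-{self.end}"
            )


@dataclass
class BlockModel:
    """A conserved block: width-w position probability matrix over 20 residues.

    ``matrix[j, r]`` is the probability of residue ``r`` at block position
    ``j``; ``background`` is the null residue distribution used for log-odds
    scoring.  The consensus string is the per-column argmax.
    """

    block_id: int
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=uniform_background)
    domain_tag: str = "NONE"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(f"block {self.block_id}: matrix must be (width, 20)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"block {self.block_id}: matrix columns must sum to 1")
        if self.background.shape != (20,) or not np.isclose(
            self.background.sum(), 1.0, atol=1e-9
        ):
            raise ValueError(f"block {self.block_id}: invalid background")
        if self.domain_tag not in DOMAIN_TAGS:
            raise ValueError(f"block {self.block_id}: bad domain tag {self.domain_tag!r}")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[j] for j in self.matrix.argmax(axis=1))

    @classmethod
    def from_consensus(
        cls,
        block_id: int,
        consensus: str,
        match_prob: float = 0.9,
        domain_tag: str = "NONE",
        background: Optional[np.ndarray] = None,
    ) -> "BlockModel":
        """Build a model putting ``match_prob`` on each consensus residue and
        spreading the remainder uniformly over the other 19 residues."""
        if not (1.0 / 20.0 < match_prob <= 1.0):
            raise ValueError("match_prob must be in (1/20, 1]")
        w = len(consensus)
        mat = np.full((w, 20), (1.0 - match_prob) / 19.0)
        for j, aa in enumerate(consensus):
            r = AA_INDEX.get(aa)
            if r is None:
                raise ValueError(
                    f"block {block_id}: consensus residue {aa!r} is not a standard amino acid"
                )
            mat[j, r] = match_prob
        bg = uniform_background() if background is None else background
        return cls(block_id=block_id, matrix=mat, background=bg, domain_tag=domain_tag)


@dataclass(frozen=True)
class BlockOccurrence:
    """A scored, positioned block hit on a protein (start is 1-based)."""

    protein_id: str
    block_id: int
    start: int
    score: float
    p_value: float
    width: int

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + self.width - 1


@dataclass
class Architecture:
    """The start-ordered, non-overlapping block hits along one protein."""

    protein_id: str
    occurrences: list[BlockOccurrence]

    def __post_init__(self) -> None:
        self.occurrences = sorted(self.occurrences, key=lambda o: o.start)
        prev_end = 0
        for occ in self.occurrences:
            if occ.start <= prev_end:
                raise ValueError(
                    f"{self.protein_id}: overlapping occurrences at {occ.start}"
                )
            prev_end = occ.end

    @property
    def block_string(self) -> list[int]:
        return [o.block_id for o in self.occurrences]


@dataclass
class CladeConsensus:
    """A clade's ordered list of blocks present in >= threshold of members."""

    clade_id: str
    member_count: int
    threshold: float
    ordered_blocks: list[int]
    specific_blocks: set[int] = field(default_factory=set)


@dataclass(frozen=True)
class DomainSeries:
    """A named maximal run of consensus blocks of a single domain class."""

    name: str
    blocks: tuple[int, ...]
    domain_class: str


@dataclass(frozen=True)
class MotifHit:
    """A functional-motif site: 1-based position of the modified residue."""

    protein_id: str
    motif_name: str
    position: int
    context: str


def unique_ids(records: Iterable) -> None:
    """Raise if two records share an id."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def as_sequences(proteins: Sequence) -> list[str]:
    """Accept ProteinRecords or plain strings; return the sequence strings."""
    out = []
    for p in proteins:
        out.append(p.sequence if isinstance(p, ProteinRecord) else str(p))
    return out
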