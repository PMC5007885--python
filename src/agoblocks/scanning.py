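"""MAST-style scanning of block models along proteins.

Every width-w window of a protein is scored with the block's log-odds matrix
(bits); the null distribution of the score under the background — with
scores discretized to a lattice of 1/100 bit per column — is computed
exactly by dynamic-programming convolution, giving each hit an exact site
p-value.  Hits with p <= threshold are selected greedily by ascending
p-value (ties: smaller start, then smaller block id), discarding candidates
that overlap an accepted hit; the surviving, start-ordered hits form the
protein's block architecture.  Multiple non-overlapping copies of one block
are allowed, which is how N-terminal glycine/arginine repeat runs are
recovered.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .models import (
    Architecture,
    BlockModel,
    BlockOccurrence,
    ProteinRecord,
    X_INDEX,
    encode,
)

#: Lattice resolution: scores are discretized to centibits.
SCORE_SCALE = 100

DEFAULT_P_THRESHOLD = 1e-4


def score_site(model: BlockModel, window: str) -> float:
    """Exact log-odds score of one window in bits; 'X' contributes 0."""
    if len(window) != model.width:
        raise ValueError(
            f"window length {len(window)} != model width {model.width}"
        )
    enc = encode(window)
    logodds = _logodds_bits(model)
    return float(sum(logodds[j, enc[j]] for j in range(model.width)))


def _logodds_bits(model: BlockModel) -> np.ndarray:
    """(w, 21) log2(p/bg); the X column is 0."""
    out = np.zeros((model.width, 21))
    out[:, :20] = np.log2(np.maximum(model.matrix, 1e-300)) - np.log2(model.background)
    return out


def _centibit_matrix(model: BlockModel) -> np.ndarray:
    """Per-column integer scores on the 1/100-bit lattice (X column 0)."""
    return np.rint(_logodds_bits(model) * SCORE_SCALE).astype(np.int64)


def _null_distribution(model: BlockModel) -> tuple[int, np.ndarray]:
    """Exact pmf of the lattice score of a background window.

    Returns (lowest lattice value, pmf array); independent columns, residues
    drawn from the model background over the 20 standard amino acids.
    """
    cb = _centibit_matrix(model)[:, :20]
    bg = model.background
    pmf = np.array([1.0])
    lo = 0
    for j in range(model.width):
        cmin = int(cb[j].min())
        cmax = int(cb[j].max())
        out = np.zeros(len(pmf) + (cmax - cmin))
        for r in range(20):
            shift = int(cb[j, r]) - cmin
            out[shift : shift + len(pmf)] += bg[r] * pmf
        pmf = out
        lo += cmin
    return lo, pmf


def _tail(pmf: np.ndarray) -> np.ndarray:
    """tail[i] = P(S >= lo + i)."""
    return pmf[::-1].cumsum()[::-1]


def site_pvalue(model: BlockModel, score: float) -> float:
    """Exact p-value P(S >= score) of the discretized score under the null.

    ``score`` is in bits; it is rounded to the same 1/100-bit lattice used
    for the null.  Scores at or below the null minimum give p = 1; scores
    above the maximum clamp to the smallest positive tail mass.
    """
    lo, pmf = _null_distribution(model)
    tail = _tail(pmf)
    idx = int(round(score * SCORE_SCALE)) - lo
    if idx <= 0:
        return 1.0
    if idx >= len(tail):
        idx = len(tail) - 1
    return float(max(tail[idx], np.finfo(float).tiny))


class Scanner:
    """Scan a fixed model set at a fixed p-value threshold.

    Precomputes, per model, the lattice score matrix, the exact null tail and
    the minimum lattice score whose tail mass is <= ``p_threshold``.
    """

    def __init__(
        self, models: Sequence[BlockModel], p_threshold: float = DEFAULT_P_THRESHOLD
    ):
        if not (0.0 < p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        self.p_threshold = p_threshold
        self.models = list(models)
        ids = [m.block_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate block ids in model set")
        self._cb: dict[int, np.ndarray] = {}
        self._lo: dict[int, int] = {}
        self._tail: dict[int, np.ndarray] = {}
        self._smin: dict[int, Optional[int]] = {}
        for m in self.models:
            cb = _centibit_matrix(m)
            lo, pmf = _null_distribution(m)
            tail = _tail(pmf)
            ok = np.flatnonzero(tail <= p_threshold)
            self._cb[m.block_id] = cb
            self._lo[m.block_id] = lo
            self._tail[m.block_id] = tail
            # smallest lattice score reaching the threshold; None if unreachable
            self._smin[m.block_id] = int(ok[0]) + lo if ok.size else None

    def _pvalue(self, block_id: int, lattice_score: int) -> float:
        idx = lattice_score - self._lo[block_id]
        tail = self._tail[block_id]
        if idx <= 0:
            return 1.0
        if idx >= len(tail):
            idx = len(tail) - 1
        return float(max(tail[idx], np.finfo(float).tiny))

    def candidates(self, protein: ProteinRecord) -> list[BlockOccurrence]:
        """All windows of all models with p <= threshold (possibly overlapping)."""
        enc = encode(protein.sequence)
        L = len(enc)
        out: list[BlockOccurrence] = []
        for m in self.models:
            w = m.width
            if L < w or self._smin[m.block_id] is None:
                continue
            cb = self._cb[m.block_id]
            n = L - w + 1
            s = np.zeros(n, dtype=np.int64)
            for j in range(w):
                s += cb[j][enc[j : j + n]]
            hits = np.flatnonzero(s >= self._smin[m.block_id])
            for t in hits:
                out.append(
                    BlockOccurrence(
                        protein_id=protein.id,
                        block_id=m.block_id,
                        start=int(t) + 1,
                        score=float(s[t]) / SCORE_SCALE,
                        p_value=self._pvalue(m.block_id, int(s[t])),
                        width=w,
                    )
                )
        return out

    def scan(self, protein: ProteinRecord) -> Architecture:
        return Architecture(
            protein_id=protein.id,
            occurrences=select_nonoverlapping(self.candidates(protein), len(protein)),
        )


def select_nonoverlapping(
    candidates: Iterable[BlockOccurrence], protein_length: int
) -> list[BlockOccurrence]:
    """Greedy selection by ascending (p-value, start, block_id); a candidate
    overlapping an already accepted hit is discarded."""
    occupied = np.zeros(protein_length + 2, dtype=bool)
    accepted: list[BlockOccurrence] = []
    for occ in sorted(candidates, key=lambda o: (o.p_value, o.start, o.block_id)):
        if not occupied[occ.start : occ.end + 1].any():
            occupied[occ.start : occ.end + 1] = True
            accepted.append(occ)
    return sorted(accepted, key=lambda o: o.start)


def scan_protein(
    models: Sequence[BlockModel],
    protein: ProteinRecord,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> Architecture:
    """Scan one protein against a model set; returns its architecture.

    A protein shorter than every model width yields an empty architecture.
    """
    return Scanner(models, p_threshold).scan(protein)


def scan_proteins(
    models: Sequence[BlockModel],
    proteins: Sequence[ProteinRecord],
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[Architecture]:
    scanner = Scanner(models, p_threshold)
    return [scanner.scan(p) for p in proteins]


def count_block_copies(
    architecture: Architecture, block_id: int, region_end: int = 0
) -> int:
    """Occurrences of ``block_id`` starting at or before ``region_end``
    (0 means the whole protein)."""
    if region_end < 0:
        raise ValueError("region_end must be >= 0")
    return sum(
        1
        for o in architecture.occurrences
        if o.block_id == block_id and (region_end == 0 or o.start <= region_end)
    )
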