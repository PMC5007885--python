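"""Conserved-block discovery by iterative single-motif ZOOPS EM.

The search emulates a MEME-style protein motif scan at desk scale: up to
``max_motifs`` rounds, each fitting one motif under the ZOOPS model (zero or
one occurrence per sequence) by expectation-maximization, over a grid of
candidate widths between 8 and 50.  Seeding is deterministic: actual data
substrings ranked by how many near-identical substrings (Hamming distance
<= ceil(w/4)) occur across the family.  An accepted motif's maximum-
likelihood site is masked with 'X' in every contributing sequence before the
next round, so no (sequence, offset) site is claimed twice.

The stop rule is a BIC-style penalized likelihood: a motif is accepted while

    significance = -(LLR - 0.5 * (19 * w) * ln(n_sequences))  <  threshold

with LLR the observed-data log-likelihood ratio against the background-only
model (in nats) and n_sequences the number of ZOOPS units.  This
replaces the E-value heuristics of production motif finders with a
deterministic, testable criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .models import (
    BlockModel,
    X_INDEX,
    as_sequences,
    encode,
    uniform_background,
)

logger = logging.getLogger(__name__)

DEFAULT_WIDTH_GRID = (8, 11, 15, 21, 29, 41, 50)


@dataclass
class DiscoveryConfig:
    """Tunable parameters of the block search."""

    max_motifs: int = 50
    width_min: int = 8
    width_max: int = 50
    width_grid: tuple[int, ...] = DEFAULT_WIDTH_GRID
    zoops_gamma_init: float = 0.5
    em_tol: float = 1e-4
    em_max_iter: int = 100
    significance_threshold: float = 0.0
    pseudocount: float = 0.01
    seed: int = 0
    n_seeds: int = 5
    seed_match_prob: float = 0.7
    seed_query_pool: int = 200
    seed_window_pool: int = 10000
    max_shift: int = 3
    trim_ic: float = 1.0  # nats; flank/core trimming threshold, 0 disables
    stop_patience: int = 3  # consecutive barren rounds tolerated before stopping

    def __post_init__(self) -> None:
        grid = tuple(w for w in self.width_grid if self.width_min <= w <= self.width_max)
        if not grid:
            raise ValueError("width_grid has no widths within [width_min, width_max]")
        self.width_grid = grid
        if self.em_tol <= 0:
            raise ValueError("em_tol must be positive")


@dataclass
class DiscoveredMotif:
    """A fitted motif: block model plus its ZOOPS fit diagnostics."""

    model: BlockModel
    zoops_gamma: float
    log_likelihood_ratio: float
    site_count: int
    significance: float
    n_iterations: int = 0
    ml_sites: list[tuple[int, int]] = field(default_factory=list)  # (seq_idx, offset)
    ll_trace: list[float] = field(default_factory=list)  # observed ll per iteration

    @property
    def consensus(self) -> str:
        return self.model.consensus

    @property
    def width(self) -> int:
        return self.model.width


# ---------------------------------------------------------------------------
# Window bookkeeping
# ---------------------------------------------------------------------------

class _WindowSet:
    """All width-w windows of a set of encoded sequences, concatenated."""

    def __init__(self, encoded: Sequence[np.ndarray], width: int):
        self.width = width
        self.seq_index: list[int] = []  # original index of each used sequence
        mats = []
        counts = []
        for i, enc in enumerate(encoded):
            if len(enc) < width:
                continue
            self.seq_index.append(i)
            mats.append(np.lib.stride_tricks.sliding_window_view(enc, width))
            counts.append(len(enc) - width + 1)
        if not mats:
            raise ValueError(f"no sequence of length >= {width}")
        self.windows = np.concatenate(mats)  # (N, w) int8
        self.m = np.array(counts)  # offsets per used sequence
        self.starts = np.concatenate([[0], np.cumsum(self.m)[:-1]])
        self.n_seqs = len(self.m)
        self.n_windows = int(self.m.sum())

    def scores(self, log_ratio: np.ndarray) -> np.ndarray:
        """Per-window sum of log(p/bg) with 'X' contributing 0; in nats."""
        s = np.zeros(self.n_windows)
        W = self.windows
        for j in range(self.width):
            s += log_ratio[j][W[:, j]]
        return s


def _log_ratio_matrix(model_matrix: np.ndarray, background: np.ndarray) -> np.ndarray:
    """(w, 21) natural-log odds; last column (X) is 0."""
    w = model_matrix.shape[0]
    out = np.zeros((w, 21))
    # floor keeps degenerate (probability-0) entries finite
    out[:, :20] = np.log(np.maximum(model_matrix, 1e-300)) - np.log(background)
    return out


# ---------------------------------------------------------------------------
# ZOOPS EM
# ---------------------------------------------------------------------------

def _e_step(ws: _WindowSet, log_ratio: np.ndarray, gamma: float):
    """Posterior over {no site} + {offsets} per sequence.

    Returns (log-likelihood ratio vs background, per-window site posterior,
    per-sequence total site posterior).
    """
    s = ws.scores(log_ratio)
    log_prior = np.log(gamma) - np.log(ws.m)  # per sequence, log(gamma/m_i)
    t = s + np.repeat(log_prior, ws.m)
    # per-sequence logsumexp over offsets
    seg_max = np.maximum.reduceat(t, ws.starts)
    sumexp = np.add.reduceat(np.exp(t - np.repeat(seg_max, ws.m)), ws.starts)
    log_site = seg_max + np.log(sumexp)
    ll_per_seq = np.logaddexp(np.log1p(-gamma), log_site)
    z = np.exp(t - np.repeat(ll_per_seq, ws.m))  # window posteriors
    site_post = np.exp(log_site - ll_per_seq)  # per-sequence P(has site)
    return float(ll_per_seq.sum()), z, site_post


def _m_step(
    ws: _WindowSet, z: np.ndarray, site_post: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, float]:
    w = ws.width
    counts = np.zeros((w, 20))
    W = ws.windows
    for j in range(w):
        counts[j] = np.bincount(W[:, j], weights=z, minlength=21)[:20]
    matrix = counts + pseudocount
    matrix /= matrix.sum(axis=1, keepdims=True)
    gamma = float(np.clip(site_post.mean(), 1e-6, 1.0 - 1e-6))
    return matrix, gamma


def _significance(llr: float, width: int, n_seqs: int) -> float:
    """BIC-style penalized likelihood; negative = significant.

    The sample size is the number of sequences — the independent units of
    the ZOOPS model (one zero-or-one site decision each).  Counting windows
    instead would overstate n by ~3 orders of magnitude and push real
    motifs confined to one small clade below the detection floor.
    """
    return -(llr - 0.5 * (19.0 * width) * np.log(n_seqs))


def em_refine(
    seed_model: BlockModel,
    sequences: Sequence,
    gamma_init: float = 0.5,
    em_tol: float = 1e-4,
    em_max_iter: int = 100,
    pseudocount: float = 0.01,
    _window_set: Optional[_WindowSet] = None,
) -> DiscoveredMotif:
    """Fit one ZOOPS motif by EM starting from ``seed_model``.

    The observed-data log-likelihood (relative to the background-only model,
    so it starts at <= 0 influence and is exactly 0 when gamma -> 0) is
    non-decreasing across iterations; iteration stops when its relative
    change falls below ``em_tol`` or after ``em_max_iter`` iterations.
    """
    if _window_set is None:
        encoded = [encode(s) for s in as_sequences(sequences)]
        short = [i for i, e in enumerate(encoded) if len(e) < seed_model.width]
        if short:
            raise ValueError(
                f"sequence(s) {short} shorter than motif width {seed_model.width}"
            )
        ws = _WindowSet(encoded, seed_model.width)
    else:
        ws = _window_set
    bg = seed_model.background
    matrix = seed_model.matrix.copy()
    gamma = float(gamma_init)
    ll_prev = -np.inf
    ll = 0.0
    z = site_post = None
    n_iter = 0
    trace: list[float] = []
    for n_iter in range(1, em_max_iter + 1):
        ll, z, site_post = _e_step(ws, _log_ratio_matrix(matrix, bg), gamma)
        if not np.isfinite(ll):
            raise ValueError("non-finite likelihood during EM")
        trace.append(ll)
        if ll_prev > -np.inf and abs(ll - ll_prev) < em_tol * max(1.0, abs(ll)):
            break
        ll_prev = ll
        matrix, gamma = _m_step(ws, z, site_post, pseudocount)
    fitted = BlockModel(block_id=seed_model.block_id, matrix=matrix, background=bg)
    # ML site per contributing sequence (site posterior > 0.5)
    ml_sites = []
    for k in range(ws.n_seqs):
        if site_post[k] > 0.5:
            lo = ws.starts[k]
            off = int(np.argmax(z[lo : lo + ws.m[k]]))
            ml_sites.append((ws.seq_index[k], off))
    return DiscoveredMotif(
        model=fitted,
        zoops_gamma=gamma,
        log_likelihood_ratio=ll,
        site_count=len(ml_sites),
        significance=_significance(ll, ws.width, ws.n_seqs),
        n_iterations=n_iter,
        ml_sites=ml_sites,
        ll_trace=trace,
    )


def zoops_posteriors(
    model: BlockModel, sequences: Sequence, gamma: float
) -> list[np.ndarray]:
    """Per-sequence posterior vectors [P(no site), P(site at 0), ...].

    Exposed for oracle testing of the E-step.
    """
    encoded = [encode(s) for s in as_sequences(sequences)]
    ws = _WindowSet(encoded, model.width)
    _, z, site_post = _e_step(ws, _log_ratio_matrix(model.matrix, model.background), gamma)
    out = []
    for k in range(ws.n_seqs):
        lo = ws.starts[k]
        vec = np.concatenate([[1.0 - site_post[k]], z[lo : lo + ws.m[k]]])
        out.append(vec)
    return out


# ---------------------------------------------------------------------------
# Deterministic seeding
# ---------------------------------------------------------------------------

def _propose_seeds(
    ws: _WindowSet, config: DiscoveryConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Top substrings ranked by the count of substrings within Hamming
    distance ceil(w/4) across the family (both sides subsampled at desk
    scale); ties broken by the substring itself for determinism."""
    w = ws.width
    clean = np.flatnonzero((ws.windows != X_INDEX).all(axis=1))
    if clean.size == 0:
        return []
    n_q = min(config.seed_query_pool, clean.size)
    n_w = min(config.seed_window_pool, clean.size)
    # query pool: windows with exact duplicates across the family first
    # (conserved-block instances collide exactly at realistic conservation,
    # background windows essentially never do), then a random fill
    contig = np.ascontiguousarray(ws.windows[clean])
    as_void = contig.view(np.dtype((np.void, w))).ravel()
    uniq, first, dup_counts = np.unique(as_void, return_index=True, return_counts=True)
    dup_order = np.argsort(-dup_counts, kind="stable")
    # at most half the pool from duplicates so one repeat-rich region
    # cannot crowd out everything else
    dup_pick = [first[i] for i in dup_order if dup_counts[i] >= 2][: n_q // 2]
    q_set = {int(clean[i]) for i in dup_pick}
    if len(q_set) < n_q:
        for i in rng.choice(clean.size, size=min(clean.size, 4 * n_q), replace=False):
            q_set.add(int(clean[i]))
            if len(q_set) >= n_q:
                break
    q_idx = np.array(sorted(q_set))
    w_idx = clean[rng.choice(clean.size, size=n_w, replace=False)] if n_w < clean.size else clean
    pool = ws.windows[w_idx]
    radius = int(np.ceil(w / 4))
    counts = np.empty(len(q_idx), dtype=np.int64)
    queries = ws.windows[q_idx]
    chunk = max(1, (8 << 20) // max(1, pool.shape[0] * w))
    for lo in range(0, len(q_idx), chunk):
        q = queries[lo : lo + chunk]
        d = (q[:, None, :] != pool[None, :, :]).sum(axis=2)
        counts[lo : lo + chunk] = (d <= radius).sum(axis=1)
    order = sorted(
        range(len(q_idx)),
        key=lambda i: (-counts[i], queries[i].tobytes()),
    )
    # keep chosen seeds pairwise dissimilar (Hamming > radius) so one
    # dominant signal cannot claim every EM start of the round
    seeds: list[np.ndarray] = []
    for i in order:
        q = queries[i]
        if any((q != s).sum() <= radius for s in seeds):
            continue
        seeds.append(q)
        if len(seeds) >= config.n_seeds:
            break
    return seeds


def _seed_model(window: np.ndarray, match_prob: float, background: np.ndarray) -> BlockModel:
    w = len(window)
    mat = np.full((w, 20), (1.0 - match_prob) / 19.0)
    mat[np.arange(w), window] = match_prob
    return BlockModel(block_id=0, matrix=mat, background=background)


# ---------------------------------------------------------------------------
# Shift (phase) refinement
# ---------------------------------------------------------------------------

def _model_from_sites(
    encoded: Sequence[np.ndarray],
    sites: Sequence[tuple[int, int]],
    width: int,
    delta: int,
    pseudocount: float,
    background: np.ndarray,
) -> Optional[BlockModel]:
    """Count matrix from the site windows shifted by ``delta`` positions."""
    counts = np.zeros((width, 20))
    n = 0
    for seq_idx, off in sites:
        s = off + delta
        enc = encoded[seq_idx]
        if s < 0 or s + width > len(enc):
            continue
        win = enc[s : s + width]
        ok = win < 20
        counts[np.arange(width)[ok], win[ok]] += 1.0
        n += 1
    if n == 0:
        return None
    mat = counts + pseudocount
    mat /= mat.sum(axis=1, keepdims=True)
    return BlockModel(block_id=0, matrix=mat, background=background)


def _shift_refine(
    motif: DiscoveredMotif,
    encoded: Sequence[np.ndarray],
    ws: _WindowSet,
    config: DiscoveryConfig,
    background: np.ndarray,
) -> DiscoveredMotif:
    """Hill-climb over column phase: EM converges to shifted local optima
    when a seed window straddles a block boundary, so re-seed the model from
    the current ML-site windows shifted by +-delta and keep any fit with a
    better significance."""
    improved = True
    while improved:
        improved = False
        for delta in [d for k in range(1, config.max_shift + 1) for d in (-k, k)]:
            seed = _model_from_sites(
                encoded, motif.ml_sites, ws.width, delta, config.pseudocount, background
            )
            if seed is None:
                continue
            cand = em_refine(
                seed,
                [],
                gamma_init=motif.zoops_gamma,
                em_tol=config.em_tol,
                em_max_iter=config.em_max_iter,
                pseudocount=config.pseudocount,
                _window_set=ws,
            )
            if cand.significance < motif.significance - 1e-9:
                motif = cand
                improved = True
                break
    return motif


# ---------------------------------------------------------------------------
# Low-information column trimming
# ---------------------------------------------------------------------------

def _column_ic(matrix: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Per-column information content (KL vs background), in nats."""
    logm = np.log(np.maximum(matrix, 1e-300))
    return (matrix * (logm - np.log(background))).sum(axis=1)


def _core_span(ic: np.ndarray, tau: float, min_width: int) -> tuple[int, int]:
    """Best contiguous run of columns scoring above ``tau`` on average
    (maximum-sum subarray of ic - tau), grown greedily to ``min_width``.

    A fitted window that straddles a block boundary — or fuses two adjacent
    blocks across a variable-length spacer — carries near-background columns
    outside the true block; trimming to the informative core keeps masking
    aligned with the planted signal."""
    x = ic - tau
    best_sum = cur = -np.inf
    best = (0, len(ic))
    lo = 0
    for i, v in enumerate(x):
        if cur < 0:
            cur = v
            lo = i
        else:
            cur += v
        if cur > best_sum:
            best_sum = cur
            best = (lo, i + 1)
    if best_sum < 0:  # nothing informative; keep as is
        return 0, len(ic)
    s, e = best
    while e - s < min(min_width, len(ic)):
        left = ic[s - 1] if s > 0 else -np.inf
        right = ic[e] if e < len(ic) else -np.inf
        if left >= right:
            s -= 1
        else:
            e += 1
    return s, e


# ---------------------------------------------------------------------------
# Iterative discovery with masking
# ---------------------------------------------------------------------------

def discover_blocks(
    sequences: Sequence, config: Optional[DiscoveryConfig] = None
) -> list[DiscoveredMotif]:
    """Discover up to ``config.max_motifs`` conserved blocks.

    Each round fits one candidate motif per (width, seed) pair, keeps the
    best by significance, stops when the best candidate fails the
    significance threshold, and otherwise masks the accepted motif's ML site
    in every contributing sequence.  Motifs are numbered 1..k in discovery
    order.  Deterministic for a fixed config (including its seed).
    """
    config = config or DiscoveryConfig()
    seqs = as_sequences(sequences)
    if not seqs:
        raise ValueError("no input sequences")
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences for discovery")
    encoded = [encode(s).copy() for s in seqs]
    background = uniform_background()
    accepted: list[DiscoveredMotif] = []
    claimed: set[tuple[int, int]] = set()
    barren = 0
    round_idx = -1
    while len(accepted) < config.max_motifs:
        round_idx += 1
        if round_idx >= 2 * config.max_motifs:
            break
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(round_idx,))
        )
        best: Optional[DiscoveredMotif] = None
        for w in config.width_grid:
            usable = [e for e in encoded if len(e) >= w]
            if len(usable) < 2:
                continue
            ws = _WindowSet(encoded, w)
            for seed_win in _propose_seeds(ws, config, rng):
                motif = em_refine(
                    _seed_model(seed_win, config.seed_match_prob, background),
                    seqs,
                    gamma_init=config.zoops_gamma_init,
                    em_tol=config.em_tol,
                    em_max_iter=config.em_max_iter,
                    pseudocount=config.pseudocount,
                    _window_set=ws,
                )
                if best is None or motif.significance < best.significance:
                    best = motif
        if best is None or best.significance >= config.significance_threshold:
            # a barren round can reflect unlucky seeding rather than an
            # exhausted signal; re-seeding differs per round, so allow a few
            barren += 1
            if best is None or barren > config.stop_patience:
                break
            continue
        barren = 0
        if config.max_shift > 0:
            ws_best = _WindowSet(encoded, best.width)
            best = _shift_refine(best, encoded, ws_best, config, background)
        if config.trim_ic > 0:
            ic = _column_ic(best.model.matrix, background)
            # weight by non-X coverage at the ML sites: columns fitted over
            # mostly-masked positions carry few real counts and would
            # otherwise look spuriously informative
            if best.ml_sites:
                cov = np.zeros(best.width)
                for seq_idx, off in best.ml_sites:
                    win = encoded[seq_idx][off : off + best.width]
                    cov += win < 20
                ic = ic * (cov / len(best.ml_sites))
            lo_c, hi_c = _core_span(ic, config.trim_ic, config.width_min)
            if (lo_c, hi_c) != (0, best.width):
                seed = BlockModel(
                    block_id=0,
                    matrix=best.model.matrix[lo_c:hi_c],
                    background=background,
                )
                best = em_refine(
                    seed,
                    [],
                    gamma_init=best.zoops_gamma,
                    em_tol=config.em_tol,
                    em_max_iter=config.em_max_iter,
                    pseudocount=config.pseudocount,
                    _window_set=_WindowSet(encoded, hi_c - lo_c),
                )
        block_id = len(accepted) + 1
        best = replace(
            best,
            model=BlockModel(
                block_id=block_id,
                matrix=best.model.matrix,
                background=best.model.background,
            ),
        )
        # mask ML sites; skip (and drop) sites already fully claimed
        kept_sites = []
        for seq_idx, off in best.ml_sites:
            if (seq_idx, off) in claimed:
                continue
            claimed.add((seq_idx, off))
            encoded[seq_idx][off : off + best.width] = X_INDEX
            kept_sites.append((seq_idx, off))
        best.ml_sites = kept_sites
        best.site_count = len(kept_sites)
        accepted.append(best)
        logger.info(
            "motif %d: width=%d sites=%d significance=%.1f consensus=%s",
            block_id,
            best.width,
            best.site_count,
            best.significance,
            best.consensus,
        )
    return accepted
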