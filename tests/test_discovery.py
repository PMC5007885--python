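import numpy as np
import pytest

from agoblocks import simulate as sim
from agoblocks.discovery import (
    DiscoveryConfig,
    discover_blocks,
    em_refine,
    zoops_posteriors,
)
from agoblocks.models import AMINO_ACIDS, AA_INDEX, BlockModel


def _random_seq(rng, n):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


# ---------------------------------------------------------------------------
# E-step oracle
# ---------------------------------------------------------------------------

def _zoops_posterior_bruteforce(model, seq, gamma):
    """Enumerate the ZOOPS mixture by hand: P(no site) = 1-gamma, each offset
    gets gamma/m times the window likelihood ratio."""
    w = model.width
    m = len(seq) - w + 1
    weights = [1.0 - gamma]
    for off in range(m):
        lr = 1.0
        for j, aa in enumerate(seq[off : off + w]):
            r = AA_INDEX[aa]
            lr *= model.matrix[j, r] / model.background[r]
        weights.append(gamma / m * lr)
    z = np.array(weights)
    return z / z.sum()


def test_e_step_matches_bruteforce_enumeration():
    rng = np.random.default_rng(0)
    model = BlockModel.from_consensus(1, "MDGVKLIA", match_prob=0.8)
    seqs = [_random_seq(rng, 10) for _ in range(2)]
    # plant the consensus at offset 1 of the first sequence
    seqs[0] = seqs[0][0] + model.consensus + seqs[0][9:]
    gamma = 0.3
    got = zoops_posteriors(model, seqs, gamma)
    for seq, vec in zip(seqs, got):
        expect = _zoops_posterior_bruteforce(model, seq, gamma)
        assert np.abs(vec - expect).max() < 1e-12


# ---------------------------------------------------------------------------
# EM refinement
# ---------------------------------------------------------------------------

def _planted_dataset(consensus, n_seqs, flank, rng, presence=1.0):
    model = BlockModel.from_consensus(1, consensus, match_prob=1.0)
    seqs = []
    for _ in range(n_seqs):
        left = _random_seq(rng, int(rng.integers(3, flank)))
        right = _random_seq(rng, int(rng.integers(3, flank)))
        mid = consensus if rng.random() < presence else _random_seq(rng, len(consensus))
        seqs.append(left + mid + right)
    return seqs


def test_em_converges_to_planted_consensus():
    rng = np.random.default_rng(1)
    consensus = "MDGVKLIAWYHQNER"
    seqs = _planted_dataset(consensus, 20, 30, rng)
    seed = BlockModel.from_consensus(1, consensus, match_prob=0.7)
    motif = em_refine(seed, seqs, gamma_init=0.5, pseudocount=0.01)
    peak = motif.model.matrix.max(axis=1)
    assert motif.consensus == consensus
    assert (peak >= 0.9).all()
    assert motif.site_count == 20


def test_em_log_likelihood_nondecreasing():
    rng = np.random.default_rng(2)
    seqs = _planted_dataset("WYHQNERCKL", 15, 25, rng)
    seed = BlockModel.from_consensus(1, "WYHQNERCKL", match_prob=0.55)
    motif = em_refine(seed, seqs, gamma_init=0.3)
    trace = np.array(motif.ll_trace)
    assert len(trace) >= 2
    diffs = np.diff(trace)
    assert (diffs >= -1e-7 * np.maximum(1.0, np.abs(trace[1:]))).all()


def test_em_rejects_short_sequences():
    seed = BlockModel.from_consensus(1, "MDGVKLIA", match_prob=0.7)
    with pytest.raises(ValueError, match="shorter"):
        em_refine(seed, ["MDG"], gamma_init=0.5)


# ---------------------------------------------------------------------------
# Iterative discovery
# ---------------------------------------------------------------------------

def _three_block_family(rng, n_seqs=60):
    blocks = {
        1: "MDGVKLIAWYHQNER",  # width 15
        2: "CPTSFEDYWNAKLMGHQRVIE",  # width 21
        3: "HQRKDEWLSTVANCGPIMYFEQKRDSTAW",  # width 29
    }
    models = {
        b: BlockModel.from_consensus(b, c, match_prob=0.95) for b, c in blocks.items()
    }
    seqs = []
    for _ in range(n_seqs):
        parts = [_random_seq(rng, int(rng.integers(5, 12)))]
        for b in (1, 2, 3):
            parts.append(sim.sample_instance(models[b], rng))
            parts.append(_random_seq(rng, int(rng.integers(5, 12))))
        seqs.append("".join(parts))
    return blocks, seqs


def test_discovery_recovers_three_planted_blocks():
    rng = np.random.default_rng(3)
    blocks, seqs = _three_block_family(rng)
    cfg = DiscoveryConfig(max_motifs=5, seed=3)
    motifs = discover_blocks(seqs, cfg)
    assert len(motifs) >= 3
    assert all(8 <= m.width <= 50 for m in motifs)
    matched = set()
    for consensus in blocks.values():
        budget = int(np.ceil(len(consensus) / 10))
        for m in motifs:
            short, long_ = sorted((m.consensus, consensus), key=len)
            if len(short) < 0.6 * len(consensus):
                continue
            dist = min(
                sum(a != b for a, b in zip(short, long_[o : o + len(short)]))
                for o in range(len(long_) - len(short) + 1)
            )
            if dist <= budget:
                matched.add(consensus)
                break
    assert len(matched) == 3


def test_discovery_is_deterministic():
    rng = np.random.default_rng(4)
    _, seqs = _three_block_family(rng, n_seqs=30)
    cfg = DiscoveryConfig(max_motifs=3, seed=9)
    a = discover_blocks(seqs, cfg)
    b = discover_blocks(seqs, cfg)
    assert [m.consensus for m in a] == [m.consensus for m in b]
    assert [m.significance for m in a] == [m.significance for m in b]


def test_discovery_masking_claims_each_site_once():
    rng = np.random.default_rng(5)
    _, seqs = _three_block_family(rng, n_seqs=40)
    motifs = discover_blocks(seqs, DiscoveryConfig(max_motifs=5, seed=5))
    seen = set()
    for m in motifs:
        for site in m.ml_sites:
            assert site not in seen
            seen.add(site)


def test_discovery_on_null_background_accepts_nothing():
    """i.i.d. uniform sequences should yield zero accepted motifs."""
    for run in range(8):
        rng = np.random.default_rng(100 + run)
        seqs = [_random_seq(rng, 200) for _ in range(30)]
        cfg = DiscoveryConfig(max_motifs=2, seed=run, stop_patience=0)
        assert discover_blocks(seqs, cfg) == []


def test_discovery_trivial_inputs():
    rng = np.random.default_rng(6)
    seqs = [_random_seq(rng, 50) for _ in range(5)]
    assert discover_blocks(seqs, DiscoveryConfig(max_motifs=0)) == []
    with pytest.raises(ValueError):
        discover_blocks([], DiscoveryConfig())
    with pytest.raises(ValueError):
        discover_blocks(["MDGVKLIA"], DiscoveryConfig())


def test_parameter_recovery_across_seeds():
    """Planted blocks (conservation 0.9, presence 0.95, n=50) are recovered
    in >= 90% of cases across seeds."""
    blocks = {
        1: "MDGVKLIAWYHQNER",
        2: "CPTSFEDYWNAKLMGHQRVIE",
        3: "HQRKDEWLSTVANCGPIMYFEQKRDSTAW",
    }
    recovered = total = 0
    for seed in range(4):
        rng = np.random.default_rng(200 + seed)
        models = {b: BlockModel.from_consensus(b, c, 0.9) for b, c in blocks.items()}
        seqs = []
        for _ in range(50):
            parts = [_random_seq(rng, int(rng.integers(5, 12)))]
            for b in (1, 2, 3):
                if rng.random() < 0.95:
                    parts.append(sim.sample_instance(models[b], rng))
                    parts.append(_random_seq(rng, int(rng.integers(5, 12))))
            seqs.append("".join(parts))
        motifs = discover_blocks(seqs, DiscoveryConfig(max_motifs=5, seed=seed))
        for consensus in blocks.values():
            total += 1
            budget = int(np.ceil(len(consensus) / 10))
            for m in motifs:
                short, long_ = sorted((m.consensus, consensus), key=len)
                if len(short) < 0.6 * len(consensus):
                    continue
                dist = min(
                    sum(a != b for a, b in zip(short, long_[o : o + len(short)]))
                    for o in range(len(long_) - len(short) + 1)
                )
                if dist <= budget:
                    recovered += 1
                    break
    assert recovered / total >= 0.9
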