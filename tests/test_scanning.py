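import itertools

import numpy as np
import pytest

from agoblocks import scanning as sc
from agoblocks.models import AMINO_ACIDS, BlockModel, BlockOccurrence, ProteinRecord


def _width1_model():
    """p(A) = 0.4, the remaining mass spread evenly; uniform background."""
    mat = np.full((1, 20), 0.6 / 19)
    mat[0, AMINO_ACIDS.index("A")] = 0.4
    return BlockModel(block_id=1, matrix=mat)


def _background_model(width=4):
    mat = np.full((width, 20), 1.0 / 20)
    return BlockModel(block_id=1, matrix=mat)


# ---------------------------------------------------------------------------
# score_site
# ---------------------------------------------------------------------------

def test_score_site_log_odds_example():
    # log2(0.4 / 0.05) = log2(8) = 3 bits
    assert sc.score_site(_width1_model(), "A") == pytest.approx(3.0)


def test_score_site_background_model_scores_zero():
    m = _background_model()
    for window in ("ACDE", "WWWW", "MDGV"):
        assert sc.score_site(m, window) == pytest.approx(0.0)


def test_score_site_x_contributes_zero():
    m = BlockModel.from_consensus(1, "MDGV", match_prob=0.9)
    assert sc.score_site(m, "XXXX") == pytest.approx(0.0)
    # masking one position removes exactly that column's contribution
    per_col = np.log2(0.9 / 0.05)
    assert sc.score_site(m, "MXGV") == pytest.approx(sc.score_site(m, "MDGV") - per_col)
    with pytest.raises(ValueError, match="length"):
        sc.score_site(m, "MDG")


# ---------------------------------------------------------------------------
# site_pvalue
# ---------------------------------------------------------------------------

def test_pvalue_is_one_for_background_model():
    assert sc.site_pvalue(_background_model(), 0.0) == pytest.approx(1.0)


def test_pvalue_width1_enumeration():
    # only 'A' reaches 3 bits; under the uniform null that is mass 1/20
    assert sc.site_pvalue(_width1_model(), 3.0) == pytest.approx(0.05)


@pytest.mark.parametrize("width", [1, 2, 3])
def test_pvalue_matches_bruteforce_for_small_widths(width, rng):
    """DP tail mass equals enumeration over all 20^w windows within 1e-9."""
    mat = rng.dirichlet(np.full(20, 0.5), size=width)
    model = BlockModel(block_id=1, matrix=mat)
    cb = sc._centibit_matrix(model)[:, :20]
    bg = model.background
    scores = {}
    for combo in itertools.product(range(20), repeat=width):
        s = int(sum(cb[j, r] for j, r in enumerate(combo)))
        p = float(np.prod([bg[r] for r in combo]))
        scores[s] = scores.get(s, 0.0) + p
    distinct = sorted(scores)
    for s in distinct[:: max(1, len(distinct) // 25)]:
        expected = sum(p for t, p in scores.items() if t >= s)
        assert sc.site_pvalue(model, s / sc.SCORE_SCALE) == pytest.approx(
            expected, abs=1e-9
        )


# ---------------------------------------------------------------------------
# scan_protein
# ---------------------------------------------------------------------------

def test_scan_finds_planted_consensus(table_models, rng):
    m = table_models[5]
    flank = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=60))
    seq = flank[:16] + m.consensus + flank[16:46]
    arch = sc.scan_protein([m], ProteinRecord(id="p", sequence=seq))
    assert [o.block_id for o in arch.occurrences] == [5]
    assert arch.occurrences[0].start == 17


def test_scan_short_protein_empty_architecture(table_models):
    arch = sc.scan_protein(list(table_models.values()), ProteinRecord(id="p", sequence="MDGVK"))
    assert arch.occurrences == []


def test_scan_own_consensus_top_hit_at_start_1(table_models):
    """Each fixture model scanned against its own consensus: one hit at
    start 1 carrying the model's maximum score."""
    for m in list(table_models.values())[::7] + [table_models[43]]:
        arch = sc.scan_protein([m], ProteinRecord(id="c", sequence=m.consensus))
        assert arch.occurrences[0].start == 1
        max_score = sc._centibit_matrix(m)[:, :20].max(axis=1).sum() / sc.SCORE_SCALE
        assert arch.occurrences[0].score == pytest.approx(max_score)


def test_presence_monotone_in_threshold(sharp_models, small_family):
    _, proteins, _ = small_family
    models = list(sharp_models.values())
    scanner_strict = sc.Scanner(models, 1e-6)
    scanner_mid = sc.Scanner(models, 1e-4)
    scanner_loose = sc.Scanner(models, 1e-2)
    for p in proteins[:6]:
        strict = {o.block_id for o in scanner_strict.scan(p).occurrences}
        mid = {o.block_id for o in scanner_mid.scan(p).occurrences}
        loose = {o.block_id for o in scanner_loose.scan(p).occurrences}
        assert strict <= mid <= loose


# ---------------------------------------------------------------------------
# Non-overlap selection vs exhaustive search
# ---------------------------------------------------------------------------

def _best_subset_bruteforce(cands, length):
    """All non-overlapping subsets; maximize count, then total score."""
    best = []
    best_key = (-1, -np.inf)
    for k in range(len(cands) + 1):
        for subset in itertools.combinations(cands, k):
            spans = sorted((o.start, o.end) for o in subset)
            if any(b <= e for (_, e), (b, _) in zip(spans, spans[1:])):
                continue
            key = (len(subset), sum(o.score for o in subset))
            if key > best_key:
                best_key = key
                best = sorted(subset, key=lambda o: o.start)
    return best


def _occ(block_id, start, width, p, score):
    return BlockOccurrence(
        protein_id="p", block_id=block_id, start=start, score=score, p_value=p, width=width
    )


def test_greedy_overlap_resolution_matches_exhaustive():
    # overlapping pair: the smaller p-value wins
    a = _occ(1, 5, 10, 1e-8, 30.0)
    b = _occ(2, 10, 10, 1e-5, 20.0)
    got = sc.select_nonoverlapping([a, b], 40)
    assert got == _best_subset_bruteforce([a, b], 40) == [a]
    # equal p-values: leftmost kept
    c = _occ(1, 5, 10, 1e-6, 25.0)   # covers 5-14
    d = _occ(2, 16, 10, 1e-6, 25.0)  # covers 16-25
    e = _occ(3, 10, 10, 1e-6, 25.0)  # overlaps both
    got = sc.select_nonoverlapping([c, d, e], 40)
    assert [o.start for o in got] == [5, 16]
    assert got == _best_subset_bruteforce([c, d, e], 40)
    # a chain where greedy and exhaustive agree on count and score
    f = _occ(1, 1, 12, 1e-9, 40.0)
    g = _occ(2, 14, 12, 1e-7, 33.0)
    h = _occ(3, 27, 12, 1e-7, 33.0)
    i = _occ(4, 20, 12, 1e-4, 15.0)  # overlaps g and h
    got = sc.select_nonoverlapping([f, g, h, i], 40)
    assert got == _best_subset_bruteforce([f, g, h, i], 40) == [f, g, h]


def test_greedy_selection_is_maximal(rng):
    """No rejected candidate could be added back without an overlap."""
    for _ in range(25):
        cands = []
        for k in range(8):
            start = int(rng.integers(1, 30))
            width = int(rng.integers(4, 12))
            cands.append(_occ(k, start, width, float(rng.random()), float(rng.random() * 20)))
        got = sc.select_nonoverlapping(cands, 45)
        starts = {(o.block_id, o.start) for o in got}
        for cand in cands:
            if (cand.block_id, cand.start) in starts:
                continue
            overlaps = any(
                not (cand.end < o.start or cand.start > o.end) for o in got
            )
            assert overlaps


# ---------------------------------------------------------------------------
# count_block_copies
# ---------------------------------------------------------------------------

def test_count_block_copies(table_models, rng):
    m = table_models[43]
    flank = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=120))
    seq = m.consensus * 3 + flank
    arch = sc.scan_protein([m], ProteinRecord(id="p", sequence=seq))
    assert sc.count_block_copies(arch, 43, region_end=100) == 3
    assert sc.count_block_copies(arch, 43, region_end=0) == 3
    assert sc.count_block_copies(arch, 43, region_end=1) == 1
    assert sc.count_block_copies(arch, 99) == 0
    with pytest.raises(ValueError):
        sc.count_block_copies(arch, 43, region_end=-1)
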