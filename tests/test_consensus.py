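import statistics

import pytest

from agoblocks import consensus as cons
from agoblocks import io as agio
from agoblocks.models import Architecture, BlockOccurrence


def _arch(pid, blocks, starts=None, width=10):
    starts = starts or [1 + i * (width + 2) for i in range(len(blocks))]
    occs = [
        BlockOccurrence(protein_id=pid, block_id=b, start=s, score=10.0,
                        p_value=1e-6, width=width)
        for b, s in zip(blocks, starts)
    ]
    return Architecture(protein_id=pid, occurrences=occs)


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------

def test_presence_collapses_copies():
    arch = _arch("p", [43, 43, 43, 43, 43])
    m = cons.build_presence_matrix([arch], {"p": "c"})
    assert list(m.presence.columns) == [43]
    assert m.presence.loc["p", 43]


def test_empty_architecture_all_false_row():
    m = cons.build_presence_matrix(
        [_arch("a", [1, 2]), Architecture(protein_id="b", occurrences=[])],
        {"a": "c", "b": "c"},
    )
    assert not m.presence.loc["b"].any()


def test_presence_requires_group():
    with pytest.raises(ValueError, match="without group"):
        cons.build_presence_matrix([_arch("p", [1])], {})


# ---------------------------------------------------------------------------
# Clade consensus
# ---------------------------------------------------------------------------

def _ten_member_matrix(present_in):
    archs = []
    groups = {}
    for i in range(10):
        pid = f"p{i}"
        groups[pid] = "c"
        blocks = [1] + ([2] if i < present_in else [])
        archs.append(_arch(pid, blocks))
    return cons.build_presence_matrix(archs, groups), archs


def test_consensus_boundary_nine_of_ten_included():
    m, archs = _ten_member_matrix(9)
    cc = cons.clade_consensus(m, "c", archs, threshold=0.90)
    assert 2 in cc.ordered_blocks  # 9/10 = 0.90 passes the >= rule


def test_consensus_eight_of_ten_excluded():
    m, archs = _ten_member_matrix(8)
    cc = cons.clade_consensus(m, "c", archs, threshold=0.90)
    assert 2 not in cc.ordered_blocks


def test_consensus_median_rank_ordering():
    # members (1,2,3), (2,1,3), (2,3); blocks 2 and 3 are consensus at 0.9:
    # ranks of 2 -> [2,1,1] (median 1), ranks of 3 -> [3,3,2] (median 3)
    archs = [
        _arch("a", [1, 2, 3]),
        _arch("b", [2, 1, 3]),
        _arch("c", [2, 3]),
    ]
    groups = {p: "k" for p in "abc"}
    m = cons.build_presence_matrix(archs, groups)
    cc = cons.clade_consensus(m, "k", archs, threshold=0.9)
    assert cc.ordered_blocks == [2, 3]


def test_consensus_empty_clade_errors():
    m, archs = _ten_member_matrix(9)
    with pytest.raises(ValueError, match="no members"):
        cons.clade_consensus(m, "ghost", archs)


def test_consensus_threshold_monotonicity(rng):
    for _ in range(20):
        archs, groups = _random_family(rng)
        m = cons.build_presence_matrix(archs, groups)
        clade = next(iter(m.clades))
        low = set(cons.clade_consensus(m, clade, archs, threshold=0.6).ordered_blocks)
        high = set(cons.clade_consensus(m, clade, archs, threshold=0.95).ordered_blocks)
        assert high <= low


# ---------------------------------------------------------------------------
# Clade-specific blocks and group consensus
# ---------------------------------------------------------------------------

def test_clade_specific_rules():
    archs = (
        [_arch(f"a{i}", [7] if i < 3 else [1]) for i in range(5)]
        + [_arch(f"b{i}", [1, 2]) for i in range(4)]
    )
    groups = {a.protein_id: ("c1" if a.protein_id.startswith("a") else "c2") for a in archs}
    m = cons.build_presence_matrix(archs, groups)
    spec = cons.clade_specific_blocks(m)
    assert spec["c1"] == {7}  # block in 3/5 of c1, nowhere else
    assert spec["c2"] == {2}
    # block 1 is in both clades -> specific to none


def test_group_consensus_two_of_four_rule():
    sets = [{1, 2}, {2, 3}, {3, 4}, {4, 5}]
    got = cons.group_consensus(sets, k=2)
    assert got == {2, 3, 4}  # each appears in exactly two sets; 1 and 5 in one
    with pytest.raises(ValueError):
        cons.group_consensus(sets, k=0)


def test_group_consensus_on_packaged_clade_architectures():
    """Block 24 sits in all four clade consensus architectures; block 46 is
    AGO4/6/8/9-specific and in none of them."""
    archs = agio.clade_architectures()
    sets = [set(v) for v in archs.values()]
    group = cons.group_consensus(sets, k=2)
    assert 24 in group
    assert 46 not in group


# ---------------------------------------------------------------------------
# Domain series naming
# ---------------------------------------------------------------------------

def test_name_domain_series_ago1_10():
    archs = agio.clade_architectures()
    series = cons.name_domain_series(archs["AGO1/10"])
    assert [s.name for s in series] == ["A-1", "DUF1785-1", "PAZ-1", "B-1", "PIWI-1"]


def test_name_domain_series_run_matching():
    assert [s.name for s in cons.name_domain_series([27, 33, 6])] == ["DUF1785-2"]
    assert cons.name_domain_series([]) == []
    # an unknown run of a known class falls back to "<class>-new"
    out = cons.name_domain_series([27, 6, 33])
    assert out[0].name == "DUF1785-new"
    assert out[0].blocks == (27, 6, 33)


# ---------------------------------------------------------------------------
# Brute-force oracle over random presence matrices
# ---------------------------------------------------------------------------

def _random_family(rng, max_proteins=8, max_blocks=8, max_clades=3):
    n_prot = int(rng.integers(2, max_proteins + 1))
    n_blocks = int(rng.integers(1, max_blocks + 1))
    n_clades = int(rng.integers(2, max_clades + 1))
    archs, groups = [], {}
    for i in range(n_prot):
        pid = f"p{i}"
        groups[pid] = f"c{int(rng.integers(0, n_clades))}"
        blocks = [b + 1 for b in range(n_blocks) if rng.random() < 0.5]
        order = rng.permutation(len(blocks))
        archs.append(_arch(pid, [blocks[j] for j in order]))
    # make sure every clade label exists
    for c in range(n_clades):
        pid = f"q{c}"
        groups[pid] = f"c{c}"
        archs.append(_arch(pid, [1] if n_blocks else []))
    return archs, groups


def _naive_consensus(archs, groups, clade, threshold):
    members = [a for a in archs if groups[a.protein_id] == clade]
    blocks = sorted({o.block_id for a in members for o in a.occurrences})
    included = []
    for b in blocks:
        count = sum(1 for a in members if b in a.block_string)
        if count / len(members) >= threshold:
            included.append(b)

    def key(b):
        ranks = [a.block_string.index(b) + 1 for a in members if b in a.block_string]
        starts = [
            min(o.start for o in a.occurrences if o.block_id == b)
            for a in members
            if b in a.block_string
        ]
        return (statistics.median(ranks), statistics.fmean(starts), b)

    return sorted(included, key=key)


def _naive_specific(archs, groups):
    clades = sorted(set(groups[a.protein_id] for a in archs))
    out = {c: set() for c in clades}
    blocks = sorted({o.block_id for a in archs for o in a.occurrences})
    for b in blocks:
        where = {
            groups[a.protein_id] for a in archs if b in a.block_string
        }
        if len(where) == 1:
            out[next(iter(where))].add(b)
    return out


def test_consensus_calculus_matches_naive_oracle(rng):
    for _ in range(80):
        archs, groups = _random_family(rng)
        m = cons.build_presence_matrix(archs, groups)
        for clade in m.clades:
            got = cons.clade_consensus(m, clade, archs, threshold=0.9)
            assert got.ordered_blocks == _naive_consensus(archs, groups, clade, 0.9)
        assert cons.clade_specific_blocks(m) == _naive_specific(archs, groups)
        sets = [
            set(cons.clade_consensus(m, c, archs, threshold=0.9).ordered_blocks)
            for c in m.clades
        ]
        expect = {
            b
            for b in set().union(*sets)
            if sum(b in s for s in sets) >= 2
        } if sets else set()
        assert cons.group_consensus(sets, k=2) == expect


def test_specific_sets_disjoint_and_outside_group_consensus(rng):
    for _ in range(30):
        archs, groups = _random_family(rng)
        m = cons.build_presence_matrix(archs, groups)
        spec = cons.clade_specific_blocks(m)
        clades = list(spec)
        for i, a in enumerate(clades):
            for b in clades[i + 1 :]:
                assert not (spec[a] & spec[b])
        sets = [
            set(cons.clade_consensus(m, c, archs, threshold=0.9).ordered_blocks)
            for c in m.clades
        ]
        group = cons.group_consensus(sets, k=2)
        for s in spec.values():
            assert not (s & group)
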