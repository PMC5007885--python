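"""Independent brute-force oracles shared by the test modules.

These deliberately use plain loops and enumeration, not the package's own
vectorized code paths.
"""

import itertools
import statistics

import numpy as np


def naive_clade_consensus(archs, groups, clade, threshold):
    """Presence >= threshold, ordered by median first-occurrence rank,
    then mean start, then block id — all with explicit loops."""
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


def naive_specific_blocks(archs, groups):
    clades = sorted({groups[a.protein_id] for a in archs})
    out = {c: set() for c in clades}
    for b in sorted({o.block_id for a in archs for o in a.occurrences}):
        where = {groups[a.protein_id] for a in archs if b in a.block_string}
        if len(where) == 1:
            out[next(iter(where))].add(b)
    return out


def enumerate_pvalues(model, centibit_matrix):
    """Exact tail masses of the lattice score over all 20^w windows."""
    bg = model.background
    masses = {}
    for combo in itertools.product(range(20), repeat=model.width):
        s = int(sum(centibit_matrix[j, r] for j, r in enumerate(combo)))
        p = float(np.prod([bg[r] for r in combo]))
        masses[s] = masses.get(s, 0.0) + p
    return masses


def best_nonoverlapping_subset(candidates):
    """All non-overlapping subsets; maximize count, then total score."""
    best, best_key = [], (-1, -np.inf)
    for k in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, k):
            spans = sorted((o.start, o.end) for o in subset)
            if any(nb <= pe for (_, pe), (nb, _) in zip(spans, spans[1:])):
                continue
            key = (len(subset), sum(o.score for o in subset))
            if key > best_key:
                best_key, best = key, sorted(subset, key=lambda o: o.start)
    return best
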