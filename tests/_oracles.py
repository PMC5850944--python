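"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's optimized code paths (profile
bicliques, bit-parallel sweeps): selection is checked by bitmask dynamic
programming over all matchings, Boolean dynamics by dictionary-based
state-space simulation, and learning by naively scoring every clause subset
with that simulator.
"""

from __future__ import annotations

import itertools
from functools import lru_cache


# ---------------------------------------------------------------------------
# selection: best (couple count, readout gap) over all subsets and matchings
# ---------------------------------------------------------------------------

def best_matching_dp(agree, gap):
    """Max-cardinality, then max-gap matching of a bipartite graph.

    ``agree[i][j]`` says CR patient i may pair with PR patient j and
    ``gap[i][j]`` is the pair's readout gap.  Returns (count, gap_total).
    """
    n_cr = len(agree)
    n_pr = len(agree[0]) if n_cr else 0

    @lru_cache(maxsize=None)
    def go(i: int, used: int):
        if i == n_cr:
            return (0, 0.0)
        best = go(i + 1, used)  # leave CR patient i unmatched
        for j in range(n_pr):
            if agree[i][j] and not used >> j & 1:
                c, g = go(i + 1, used | 1 << j)
                cand = (c + 1, g + gap[i][j])
                if cand > best:
                    best = cand
        return best

    result = go(0, 0)
    go.cache_clear()
    return result


def best_selection_bruteforce(bits_cr, bits_pr, readouts_cr, readouts_pr, k):
    """Optimal (couple count, gap) over all k-subsets of input proteins.

    Returns ``(n_couples, gap, winning_subsets)`` where the gap is the best
    tie-break value among count-optimal subsets and matchings.
    """
    n_proteins = len(bits_cr[0])
    gap = [
        [
            sum(abs(a - b) for a, b in zip(readouts_cr[i], readouts_pr[j]))
            for j in range(len(bits_pr))
        ]
        for i in range(len(bits_cr))
    ]
    best_count, best_gap, winners = -1, -1.0, []
    for combo in itertools.combinations(range(n_proteins), k):
        agree = [
            [
                all(bits_cr[i][p] == bits_pr[j][p] for p in combo)
                for j in range(len(bits_pr))
            ]
            for i in range(len(bits_cr))
        ]
        count, g = best_matching_dp(
            tuple(tuple(r) for r in agree), tuple(tuple(r) for r in gap)
        )
        if count > best_count:
            best_count, best_gap, winners = count, g, [combo]
        elif count == best_count:
            winners.append(combo)
            best_gap = max(best_gap, g)
    return best_count, best_gap, winners


# ---------------------------------------------------------------------------
# Boolean dynamics: dictionary-based synchronous simulation
# ---------------------------------------------------------------------------

def naive_fixpoint(clauses, clamped, nodes):
    """Synchronous trajectory from the all-zero (plus clamps) state.

    ``clauses`` is a list of (target, [(regulator, sign), ...]).  Returns
    (state dict, oscillatory flag); on oscillation unclamped nodes are 0.
    """
    by_target = {}
    for target, lits in clauses:
        by_target.setdefault(target, []).append(lits)
    state = {n: clamped.get(n, 0) for n in nodes}
    for _ in range(len(nodes) + 1):
        new = {}
        for n in nodes:
            if n in clamped:
                new[n] = clamped[n]
                continue
            value = 0
            for lits in by_target.get(n, ()):
                if all(
                    (state[r] == 1) if s > 0 else (state[r] == 0) for r, s in lits
                ):
                    value = 1
                    break
            new[n] = value
        if new == state:
            return state, False
        state = new
    return {n: (clamped[n] if n in clamped else 0) for n in nodes}, True


def naive_score(clauses, experiments, nodes):
    """MSE of one clause set against experiments, via naive simulation."""
    total, cells = 0.0, 0
    for clamped, observed in experiments:
        state, osc = naive_fixpoint(clauses, clamped, nodes)
        for r, obs in observed.items():
            pred = 0 if osc else state[r]
            total += (pred - obs) ** 2
            cells += 1
    return total / cells


def naive_learn(candidate_clauses, experiments, nodes, eps=1e-9):
    """All (MSE-minimal, then size-minimal) subsets by scoring everything."""
    m = len(candidate_clauses)
    scored = []
    for mask in range(1 << m):
        subset = [candidate_clauses[i] for i in range(m) if mask >> i & 1]
        scored.append((mask, naive_score(subset, experiments, nodes), len(subset)))
    min_mse = min(s[1] for s in scored)
    fit = [s for s in scored if s[1] <= min_mse + eps]
    min_size = min(s[2] for s in fit)
    masks = sorted(s[0] for s in fit if s[2] == min_size)
    return masks, min_mse, min_size
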