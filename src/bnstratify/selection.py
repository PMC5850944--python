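"""Exact protein-set and patient-couple selection.

Given binarized input profiles for the two response classes, choose a set K
of k input proteins maximizing the number of *non-redundant* CR-PR patient
couples: pairs whose bits agree on every protein of K ("affinity"), with no
patient reused across couples.  Non-redundancy is formalized as a maximum
bipartite matching of the affinity graph.  When several selections (or
several maximum matchings) are co-optimal, the one maximizing the summed
absolute readout difference over its couples is ranked first.

Because affinity depends only on a patient's bit profile restricted to K,
the affinity graph is a disjoint union of complete bipartite blocks (one per
profile), so the maximum matching size is sum over profiles of
min(#CR, #PR) and the gap-maximal maximum matching decomposes into one
rectangular assignment problem per block.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .preprocessing import CR, PR, ProcessedDataset, split_by_class

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class Couple:
    """A matched CR-PR patient pair acting as one pseudo-perturbation."""

    cr_patient: str
    pr_patient: str


@dataclass
class SelectionResult:
    k: int
    proteins: tuple[str, ...]
    couples: list[Couple]
    affinity_count: int  # total affinity pairs (the ASP-style objective)
    readout_gap: float  # summed |r_CR - r_PR| over the returned couples

    def __post_init__(self) -> None:
        if len(self.proteins) != self.k:
            raise ValueError("|proteins| must equal k")
        crs = [c.cr_patient for c in self.couples]
        prs = [c.pr_patient for c in self.couples]
        if len(set(crs)) != len(crs) or len(set(prs)) != len(prs):
            raise ValueError("a patient appears in two couples (redundant)")
        if self.affinity_count < len(self.couples):
            raise ValueError("affinity_count cannot be below the couple count")


def affinity(inputs: pd.DataFrame, K, j: str, j_prime: str) -> int:
    """1 iff patients ``j`` and ``j_prime`` share every bit of the proteins in K."""
    K = list(K)
    if not K:
        raise ValueError("K must be non-empty")
    missing = [p for p in K if p not in inputs.columns]
    if missing:
        raise ValueError(f"proteins absent from the binarized matrix: {missing}")
    return int((inputs.loc[j, K].to_numpy() == inputs.loc[j_prime, K].to_numpy()).all())


def max_nonredundant_couples(
    affinity_pairs: list[Couple], enumerate_all: bool = False
) -> list[Couple] | list[list[Couple]]:
    """Maximum-cardinality matching of the bipartite CR/PR affinity graph.

    With ``enumerate_all`` every maximum matching is returned (backtracking;
    intended for small instances and for the readout-gap tie-break audit).
    """
    if not affinity_pairs:
        return [] if not enumerate_all else [[]]
    g = nx.Graph()
    cr_nodes = sorted({("C", c.cr_patient) for c in affinity_pairs})
    for c in affinity_pairs:
        g.add_edge(("C", c.cr_patient), ("P", c.pr_patient))
    matching = nx.bipartite.hopcroft_karp_matching(g, top_nodes=cr_nodes)
    couples = sorted(
        Couple(u[1], v[1]) for u, v in matching.items() if u[0] == "C"
    )
    if not enumerate_all:
        return couples
    return _enumerate_maximum_matchings(affinity_pairs, len(couples))


def _enumerate_maximum_matchings(pairs: list[Couple], size: int) -> list[list[Couple]]:
    neighbours: dict[str, list[str]] = {}
    for c in pairs:
        neighbours.setdefault(c.cr_patient, []).append(c.pr_patient)
    crs = sorted(neighbours)
    results: list[list[Couple]] = []

    def recurse(i: int, used: set[str], acc: list[Couple]) -> None:
        if len(acc) + (len(crs) - i) < size:
            return  # cannot reach a maximum matching any more
        if i == len(crs):
            if len(acc) == size:
                results.append(sorted(acc))
            return
        cr = crs[i]
        for pr in sorted(neighbours[cr]):
            if pr not in used:
                used.add(pr)
                acc.append(Couple(cr, pr))
                recurse(i + 1, used, acc)
                acc.pop()
                used.remove(pr)
        recurse(i + 1, used, acc)  # leave this CR patient unmatched

    recurse(0, set(), [])
    uniq = {tuple(m): m for m in results}
    return [uniq[k] for k in sorted(uniq)]


def readout_gap(
    readouts_cr: pd.DataFrame, readouts_pr: pd.DataFrame, couples: list[Couple]
) -> float:
    """Summed absolute readout difference over the couples."""
    if not couples:
        raise ValueError("couples must be non-empty")
    total = 0.0
    for c in couples:
        a = readouts_cr.loc[c.cr_patient].to_numpy(dtype=float)
        b = readouts_pr.loc[c.pr_patient].to_numpy(dtype=float)
        total += float(np.abs(a - b).sum())
    return total


# ---------------------------------------------------------------------------
# per-subset optimization via the biclique structure
# ---------------------------------------------------------------------------

def _profile_blocks(bits_cr: np.ndarray, bits_pr: np.ndarray):
    """Group CR and PR row indices by identical bit profile."""
    blocks: dict[tuple, tuple[list[int], list[int]]] = {}
    for i, row in enumerate(bits_cr):
        blocks.setdefault(tuple(row), ([], []))[0].append(i)
    for j, row in enumerate(bits_pr):
        blocks.setdefault(tuple(row), ([], []))[1].append(j)
    return [b for b in blocks.values() if b[0] and b[1]]


def _matching_size_and_affinity(blocks) -> tuple[int, int]:
    n_match = sum(min(len(a), len(b)) for a, b in blocks)
    n_aff = sum(len(a) * len(b) for a, b in blocks)
    return n_match, n_aff


def _best_gap_matching(blocks, gap_matrix: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Maximum matching maximizing the summed readout gap (block-wise assignment)."""
    couples: list[tuple[int, int]] = []
    total = 0.0
    for cr_idx, pr_idx in blocks:
        sub = gap_matrix[np.ix_(cr_idx, pr_idx)]
        rows, cols = linear_sum_assignment(sub, maximize=True)
        for r, c in zip(rows, cols):
            couples.append((cr_idx[r], pr_idx[c]))
            total += float(sub[r, c])
    return sorted(couples), total


class CoupleSelector(BaseEstimator):
    """Exhaustive exact selection of k input proteins and patient couples.

    Scans all C(n_inputs, k) protein subsets; keeps every subset attaining
    the maximal number of non-redundant couples (maximum matching of the
    affinity graph); ranks co-optimal subsets by maximal readout gap, then
    lexicographically by protein names.

    Fitted attributes: ``results_`` (ranked co-optimal selections),
    ``selection_`` (the first-ranked one), ``proteins_``, ``couples_``.
    """

    def __init__(self, k: int | None = None, strategy: str = "exhaustive"):
        self.k = k
        self.strategy = strategy

    def fit(self, proc: ProcessedDataset, y=None) -> "CoupleSelector":
        if self.strategy == "asp":
            raise ImportError(
                "the optional ASP backend requires clingo, which is not "
                "installed; use strategy='exhaustive'"
            )
        if self.strategy != "exhaustive":
            raise ValueError(f"unknown strategy {self.strategy!r}")
        cr, pr = split_by_class(proc)
        proteins = sorted(proc.inputs.columns)
        k = self.k if self.k is not None else len(proteins)
        if not 1 <= k <= len(proteins):
            raise ValueError(f"k={k} not in 1..{len(proteins)}")
        bits_cr = cr.inputs[proteins].to_numpy(dtype=np.int8)
        bits_pr = pr.inputs[proteins].to_numpy(dtype=np.int8)
        gap_matrix = cdist(
            cr.readouts.to_numpy(dtype=float),
            pr.readouts.to_numpy(dtype=float),
            metric="cityblock",
        )
        cr_ids = list(cr.inputs.index)
        pr_ids = list(pr.inputs.index)

        best = -1
        winners: list[tuple[tuple[str, ...], list, int]] = []
        for combo in itertools.combinations(range(len(proteins)), k):
            blocks = _profile_blocks(bits_cr[:, combo], bits_pr[:, combo])
            n_match, n_aff = _matching_size_and_affinity(blocks)
            if n_match > best:
                best = n_match
                winners = [(combo, blocks, n_aff)]
            elif n_match == best:
                winners.append((combo, blocks, n_aff))

        results: list[SelectionResult] = []
        if best <= 0:
            logger.warning("no affine CR-PR couple achievable for any %d-subset", k)
            self.results_ = []
            self.selection_ = None
            return self
        for combo, blocks, n_aff in winners:
            pairs, gap = _best_gap_matching(blocks, gap_matrix)
            couples = [Couple(cr_ids[i], pr_ids[j]) for i, j in pairs]
            results.append(
                SelectionResult(
                    k=k,
                    proteins=tuple(proteins[i] for i in combo),
                    couples=sorted(couples),
                    affinity_count=n_aff,
                    readout_gap=gap,
                )
            )
        results.sort(key=lambda r: (-r.readout_gap, r.proteins))
        self.results_ = results
        self.selection_ = results[0]
        self.proteins_ = self.selection_.proteins
        self.couples_ = self.selection_.couples
        return self


def select_proteins(
    proc: ProcessedDataset, k: int, strategy: str = "exhaustive"
) -> list[SelectionResult]:
    """All co-optimal k-protein selections, gap-ranked (see CoupleSelector)."""
    return CoupleSelector(k=k, strategy=strategy).fit(proc).results_


def sweep_k(proc: ProcessedDataset, k_range) -> pd.DataFrame:
    """Optimal couple count and redundant-pair count for each k.

    A redundant couple is an affinity pair sharing a patient with another
    affinity pair; with the biclique structure these are exactly the pairs of
    blocks larger than 1x1.
    """
    rows = []
    for k in k_range:
        results = select_proteins(proc, k=k)
        if not results:
            rows.append({"k": k, "n_couples": 0, "n_redundant": 0, "n_affinity": 0})
            continue
        top = results[0]
        bits = proc.inputs[list(top.proteins)]
        cr, pr = split_by_class(
            ProcessedDataset(inputs=bits, readouts=proc.readouts, labels=proc.labels)
        )
        blocks = _profile_blocks(
            cr.inputs.to_numpy(dtype=np.int8), pr.inputs.to_numpy(dtype=np.int8)
        )
        redundant = sum(
            len(a) * len(b) for a, b in blocks if len(a) * len(b) > 1
        )
        rows.append(
            {
                "k": k,
                "n_couples": len(top.couples),
                "n_redundant": redundant,
                "n_affinity": top.affinity_count,
            }
        )
    return pd.DataFrame(rows, columns=["k", "n_couples", "n_redundant", "n_affinity"])


@dataclass
class ReducedDataset:
    """Per-couple experiments of one class: shared input bits, class readouts."""

    inputs: pd.DataFrame  # index: couple number, columns: selected proteins
    readouts: pd.DataFrame  # index: couple number, columns: readout proteins
    couples: list[Couple] = field(default_factory=list)

    def to_experiments(self) -> list:
        from .learning import Experiment

        exps = []
        for i in self.inputs.index:
            clamped = {p: int(v) for p, v in self.inputs.loc[i].items()}
            observed = {r: float(v) for r, v in self.readouts.loc[i].items()}
            exps.append(Experiment(clamped=clamped, observed=observed))
        return exps


def build_reduced_datasets(
    proc: ProcessedDataset, sel: SelectionResult
) -> tuple[ReducedDataset, ReducedDataset]:
    """One experiment per couple; identical input rows, class-specific readouts."""
    if not sel.couples:
        raise ValueError("selection has no couples")
    cols = list(sel.proteins)
    idx = range(len(sel.couples))
    cr_rows, pr_rows, cr_obs, pr_obs = [], [], [], []
    for c in sel.couples:
        cr_bits = proc.inputs.loc[c.cr_patient, cols]
        pr_bits = proc.inputs.loc[c.pr_patient, cols]
        if not (cr_bits.to_numpy() == pr_bits.to_numpy()).all():
            raise ValueError(f"couple {c} does not share its input profile on K")
        cr_rows.append(cr_bits.to_numpy(dtype=int))
        pr_rows.append(pr_bits.to_numpy(dtype=int))
        cr_obs.append(proc.readouts.loc[c.cr_patient].to_numpy(dtype=float))
        pr_obs.append(proc.readouts.loc[c.pr_patient].to_numpy(dtype=float))
    robs = list(proc.readouts.columns)
    mk = lambda rows, obs: ReducedDataset(
        inputs=pd.DataFrame(rows, index=idx, columns=cols),
        readouts=pd.DataFrame(obs, index=idx, columns=robs),
        couples=list(sel.couples),
    )
    return mk(cr_rows, cr_obs), mk(pr_rows, pr_obs)
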