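"""Boolean network family learning from couple experiments.

A Boolean network is a subset of the candidate clause set (the hypergraph);
clauses sharing a target are OR-ed.  Semantics: clamped nodes hold their
value, every other node starts at 0 and is updated synchronously by its
OR-of-ANDs rule until a fixed point (cap |nodes| + 1 sweeps); a run that
fails to stabilize is flagged oscillatory and its readouts are scored 0.

Learning enumerates every clause subset and keeps those minimizing the mean
squared error against the observed readouts, then the number of clauses
(lexicographic objective, with configurable tolerances).  The synchronous
sweep is bit-parallel: each node's value across all experiments is packed
into one Python integer, so one sweep costs O(clauses) integer operations.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

from .pkn import Clause, HyperGraph

logger = logging.getLogger(__name__)

#: slack used when comparing floating-point MSE values for co-optimality
MSE_EPS = 1e-9


@dataclass
class Experiment:
    """One perturbation: clamped input bits and observed readout values."""

    clamped: dict[str, int]
    observed: dict[str, float]

    def __post_init__(self) -> None:
        for n, v in self.clamped.items():
            if v not in (0, 1):
                raise ValueError(f"clamp for {n} must be 0/1, got {v!r}")
        for n, v in self.observed.items():
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"observation for {n} must be in [0,1], got {v!r}")


@dataclass(frozen=True)
class BooleanNetwork:
    """An OR-of-ANDs logical network: a frozen set of clauses."""

    clauses: frozenset[Clause]

    @property
    def size(self) -> int:
        return len(self.clauses)

    def sorted_clauses(self) -> list[Clause]:
        return sorted(self.clauses)

    def to_json_obj(self) -> list:
        return [
            {"target": c.target, "literals": [[n, s] for n, s in c.literals]}
            for c in self.sorted_clauses()
        ]

    @classmethod
    def from_json_obj(cls, obj) -> "BooleanNetwork":
        return cls(
            frozenset(
                Clause(d["target"], tuple((n, int(s)) for n, s in d["literals"]))
                for d in obj
            )
        )


@dataclass
class BNFamily:
    """All co-optimal Boolean networks for one class, plus learning metadata."""

    networks: list[BooleanNetwork]
    fitness: float  # optimal MSE
    size: int  # clause count of the optimum
    nodes: tuple[str, ...] = ()
    clamp_nodes: tuple[str, ...] = ()
    readouts: tuple[str, ...] = ()
    behaviors: list[list[int]] | None = None  # indices into `networks`


@dataclass(frozen=True)
class ClauseFrequency:
    clause: Clause
    frequency: float


# ---------------------------------------------------------------------------
# bit-parallel synchronous fixpoint engine
# ---------------------------------------------------------------------------

class SynchronousEngine:
    """Evaluates clause subsets on a batch of clampings simultaneously.

    Experiment ``e`` occupies bit ``e`` of each node's state integer.
    """

    def __init__(self, nodes, clauses: list[Clause], clampings: list[dict[str, int]]):
        self.nodes = list(nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.clauses = list(clauses)
        self.n_exp = len(clampings)
        self.full = (1 << self.n_exp) - 1
        n = len(self.nodes)
        self.clamp_mask = [0] * n
        self.clamp_val = [0] * n
        for e, cl in enumerate(clampings):
            for node, v in cl.items():
                if node not in self.index:
                    raise ValueError(f"clamped node {node!r} not in the network")
                i = self.index[node]
                self.clamp_mask[i] |= 1 << e
                if v:
                    self.clamp_val[i] |= 1 << e
        # clause structs: (target index, ((literal index, positive?), ...))
        self._structs = [
            (self.index[c.target], tuple((self.index[n], s > 0) for n, s in c.literals))
            for c in self.clauses
        ]

    def run(self, selected) -> tuple[list[int], int]:
        """Fixpoint states for the clause subset ``selected`` (indices).

        Returns ``(states, oscillating)``: per-node bitmask of values, and a
        bitmask of experiments that failed to stabilize within |nodes| + 1
        synchronous sweeps (their bits are unreliable and scored as 0).
        """
        full = self.full
        cm, cv = self.clamp_mask, self.clamp_val
        by_target: dict[int, list] = {}
        for ci in selected:
            t, lits = self._structs[ci]
            by_target.setdefault(t, []).append(lits)
        state = list(cv)
        changed_nodes = 0
        for _ in range(len(self.nodes) + 1):
            new = list(state)
            changed = 0
            for t, clause_list in by_target.items():
                acc = 0
                for lits in clause_list:
                    term = full
                    for li, pos in lits:
                        term &= state[li] if pos else (full ^ state[li])
                        if not term:
                            break
                    acc |= term
                    if acc == full:
                        break
                val = (acc & ~cm[t]) | cv[t]
                if val != state[t]:
                    changed |= val ^ state[t]
                    new[t] = val
            state = new
            if not changed:
                return state, 0
            changed_nodes = changed
        # did not stabilize: experiments whose bits were still flipping
        return state, changed_nodes & full


def _infer_nodes(net: BooleanNetwork, clamped: dict[str, int]):
    names = set(clamped)
    for c in net.clauses:
        names.add(c.target)
        names.update(n for n, _ in c.literals)
    return sorted(names)


def fixpoint(
    net: BooleanNetwork, clamped: dict[str, int], nodes=None
) -> dict[str, int]:
    """Logical steady state of one network under one clamping.

    Clamped nodes keep their value; other nodes start at 0 and follow the
    synchronous OR-of-ANDs update.  On non-convergence the unstable nodes are
    reported as 0 with a warning (oscillatory run).
    """
    node_list = list(nodes) if nodes is not None else _infer_nodes(net, clamped)
    for c in net.clauses:
        for n, _ in c.literals:
            if n not in node_list:
                raise ValueError(f"clause regulator {n!r} outside the node universe")
    engine = SynchronousEngine(node_list, sorted(net.clauses), [clamped])
    states, osc = engine.run(range(len(net.clauses)))
    if osc:
        logger.warning("fixpoint: oscillatory run; unstable nodes reported as 0")
    out = {}
    for n in node_list:
        v = states[engine.index[n]] & 1
        out[n] = int(v) if not osc else 0 if engine.clamp_mask[engine.index[n]] == 0 else int(v)
    return out


def predict(
    family_or_net,
    clamped: dict[str, int],
    readouts,
    aggregate: str = "mean-networks",
    nodes=None,
) -> dict[str, float]:
    """Per-readout prediction: fixpoint value, averaged over a family.

    ``aggregate="mean-networks"`` averages over member networks (default);
    ``"mean-behaviors"`` averages one representative per I/O behavior group.
    """
    readouts = list(readouts)
    if isinstance(family_or_net, BooleanNetwork):
        fp = fixpoint(family_or_net, clamped, nodes=nodes)
        return {r: float(fp.get(r, 0)) for r in readouts}
    family: BNFamily = family_or_net
    if not family.networks:
        raise ValueError("empty family")
    node_list = list(nodes) if nodes is not None else list(family.nodes) or None
    if aggregate == "mean-behaviors":
        if family.behaviors is None:
            raise ValueError("family has no behavior partition; run classify_behaviors")
        members = [family.networks[g[0]] for g in family.behaviors]
    elif aggregate == "mean-networks":
        members = family.networks
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    acc = {r: 0.0 for r in readouts}
    for net in members:
        fp = fixpoint(net, clamped, nodes=node_list)
        for r in readouts:
            acc[r] += fp.get(r, 0)
    return {r: acc[r] / len(members) for r in readouts}


def mse(net_or_family, experiments: list[Experiment], readouts=None) -> float:
    """Mean of (prediction - observation)^2 over all (experiment, readout) cells."""
    if not experiments:
        raise ValueError("experiments must be non-empty")
    total, cells = 0.0, 0
    for exp in experiments:
        targets = list(readouts) if readouts is not None else sorted(exp.observed)
        preds = predict(net_or_family, exp.clamped, targets)
        for r in targets:
            if r in exp.observed:
                total += (preds[r] - exp.observed[r]) ** 2
                cells += 1
    if cells == 0:
        raise ValueError("no observed readout cells")
    return total / cells


# ---------------------------------------------------------------------------
# exhaustive family learning
# ---------------------------------------------------------------------------

def _score_subsets(
    hg: HyperGraph, experiments: list[Experiment], readouts: list[str]
):
    """Yield (mask, mse, size) for every clause subset, bit-parallel."""
    engine = SynchronousEngine(
        hg.pkn.nodes, hg.clauses, [e.clamped for e in experiments]
    )
    m = len(hg.clauses)
    n_exp = len(experiments)
    ridx = [engine.index[r] for r in readouts]
    # per readout: which experiments observe it, the observation, and weights
    obs = []
    cells = 0
    for r, ri in zip(readouts, ridx):
        entries = []
        for e, exp in enumerate(experiments):
            if r in exp.observed:
                o = float(exp.observed[r])
                entries.append((e, o * o, 1.0 - 2.0 * o))
                cells += 1
        obs.append((ri, entries))
    if cells == 0:
        raise ValueError("no observed readout cells")
    all_indices = list(range(m))
    for mask in range(1 << m):
        selected = [i for i in all_indices if mask >> i & 1]
        states, osc = engine.run(selected)
        stable = engine.full & ~osc
        total = 0.0
        for ri, entries in obs:
            bits = states[ri] & stable  # oscillatory experiments score 0
            for e, o2, w in entries:
                total += o2
                if bits >> e & 1:
                    total += w
        yield mask, total / cells, len(selected)


class BooleanFamilyLearner:
    """Exhaustive learner of the co-optimal Boolean network family.

    Parameters
    ----------
    hypergraph : HyperGraph
        Candidate clause set (the search space is 2**|clauses|).
    fit_tolerance : float
        Keep subsets with MSE within this of the global minimum (default 0).
    size_tolerance : int
        Keep subsets within this many clauses of the minimal size among the
        MSE-optimal ones (default 0).
    max_clauses : int
        Guard on the exhaustive search (default 20).
    """

    def __init__(
        self,
        hypergraph: HyperGraph,
        fit_tolerance: float = 0.0,
        size_tolerance: int = 0,
        strategy: str = "exhaustive",
        max_clauses: int = 20,
    ):
        self.hypergraph = hypergraph
        self.fit_tolerance = fit_tolerance
        self.size_tolerance = size_tolerance
        self.strategy = strategy
        self.max_clauses = max_clauses

    def get_params(self, deep: bool = True) -> dict:
        return {
            "hypergraph": self.hypergraph,
            "fit_tolerance": self.fit_tolerance,
            "size_tolerance": self.size_tolerance,
            "strategy": self.strategy,
            "max_clauses": self.max_clauses,
        }

    def set_params(self, **params) -> "BooleanFamilyLearner":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, experiments: list[Experiment], y=None) -> "BooleanFamilyLearner":
        self.family_ = learn(
            self.hypergraph,
            experiments,
            fit_tolerance=self.fit_tolerance,
            size_tolerance=self.size_tolerance,
            strategy=self.strategy,
            max_clauses=self.max_clauses,
        )
        self.mse_ = self.family_.fitness
        self.size_ = self.family_.size
        return self


def learn(
    hg: HyperGraph,
    experiments: list[Experiment],
    fit_tolerance: float = 0.0,
    size_tolerance: int = 0,
    strategy: str = "exhaustive",
    max_clauses: int = 20,
) -> BNFamily:
    """Every clause subset minimizing (MSE, then size) within tolerances."""
    if strategy == "asp":
        raise ImportError(
            "the optional ASP backend requires clingo, which is not installed; "
            "use strategy='exhaustive'"
        )
    if strategy != "exhaustive":
        raise ValueError(f"unknown strategy {strategy!r}")
    if not experiments:
        raise ValueError("experiments must be non-empty")
    m = len(hg.clauses)
    if m > max_clauses:
        raise ValueError(
            f"{m} candidate clauses exceed the exhaustive cap ({max_clauses}); "
            "reduce the hypergraph or use the ASP backend"
        )
    readouts = sorted({r for e in experiments for r in e.observed})
    clamp_nodes = sorted({n for e in experiments for n in e.clamped})
    records = list(_score_subsets(hg, experiments, readouts))
    min_mse = min(r[1] for r in records)
    fit_ok = [r for r in records if r[1] <= min_mse + fit_tolerance + MSE_EPS]
    min_size = min(r[2] for r in fit_ok)
    kept = [r for r in fit_ok if r[2] <= min_size + size_tolerance]
    networks = [
        BooleanNetwork(frozenset(hg.clauses[i] for i in range(m) if mask >> i & 1))
        for mask, _, _ in kept
    ]
    networks.sort(key=lambda n: (n.size, n.sorted_clauses()))
    return BNFamily(
        networks=networks,
        fitness=min_mse,
        size=min_size,
        nodes=tuple(hg.pkn.nodes),
        clamp_nodes=tuple(clamp_nodes),
        readouts=tuple(readouts),
    )


def classify_behaviors(
    family: BNFamily, input_nodes=None, readouts=None
) -> list[list[int]]:
    """Partition the family by input-output behavior.

    Two networks share a group when their readout fixpoints agree on all 2^n
    clampings of the input nodes.  Sets ``family.behaviors`` and returns it.
    """
    inputs = sorted(input_nodes) if input_nodes is not None else list(family.clamp_nodes)
    targets = sorted(readouts) if readouts is not None else list(family.readouts)
    if len(inputs) > 20:
        raise ValueError(
            f"{len(inputs)} inputs means 2^{len(inputs)} clampings; "
            "restrict input_nodes or sample clampings externally"
        )
    clampings = [
        {n: (pattern >> i) & 1 for i, n in enumerate(inputs)}
        for pattern in range(1 << len(inputs))
    ]
    nodes = list(family.nodes) or sorted(
        set(inputs)
        | {c.target for net in family.networks for c in net.clauses}
        | {n for net in family.networks for c in net.clauses for n, _ in c.literals}
        | set(targets)
    )
    groups: dict[tuple, list[int]] = {}
    for i, net in enumerate(family.networks):
        engine = SynchronousEngine(nodes, net.sorted_clauses(), clampings)
        states, osc = engine.run(range(net.size))
        stable = engine.full & ~osc
        sig = tuple(states[engine.index[r]] & stable for r in targets)
        groups.setdefault(sig, []).append(i)
    family.behaviors = sorted(groups.values(), key=lambda g: g[0])
    return family.behaviors


def clause_frequencies(family: BNFamily) -> list[ClauseFrequency]:
    """Fraction of member networks containing each clause, sorted descending."""
    if not family.networks:
        raise ValueError("empty family")
    counts: dict[Clause, int] = {}
    for net in family.networks:
        for c in net.clauses:
            counts[c] = counts.get(c, 0) + 1
    n = len(family.networks)
    freqs = [ClauseFrequency(c, counts[c] / n) for c in counts]
    freqs.sort(key=lambda f: (-f.frequency, f.clause))
    return freqs


def union_network(family: BNFamily) -> BooleanNetwork:
    """Clause-set union across the family (the thick-edge summary network)."""
    if not family.networks:
        raise ValueError("empty family")
    clauses = frozenset().union(*(net.clauses for net in family.networks))
    return BooleanNetwork(clauses)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def family_to_json_obj(family: BNFamily) -> dict:
    return {
        "fitness": family.fitness,
        "size": family.size,
        "nodes": list(family.nodes),
        "clamp_nodes": list(family.clamp_nodes),
        "readouts": list(family.readouts),
        "behaviors": family.behaviors,
        "networks": [net.to_json_obj() for net in family.networks],
    }


def family_from_json_obj(obj: dict) -> BNFamily:
    return BNFamily(
        networks=[BooleanNetwork.from_json_obj(n) for n in obj["networks"]],
        fitness=float(obj["fitness"]),
        size=int(obj["size"]),
        nodes=tuple(obj.get("nodes", ())),
        clamp_nodes=tuple(obj.get("clamp_nodes", ())),
        readouts=tuple(obj.get("readouts", ())),
        behaviors=obj.get("behaviors"),
    )


def write_family_json(family: BNFamily, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(family_to_json_obj(family), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_family_json(path) -> BNFamily:
    with open(path, "r", encoding="utf-8") as fh:
        return family_from_json_obj(json.load(fh))


def write_frequency_csv(family: BNFamily, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["clause", "frequency"])
        for f in clause_frequencies(family):
            w.writerow([str(f.clause), f"{f.frequency:.6g}"])


def write_family_report_csv(family: BNFamily, path) -> None:
    behavior_of = {}
    if family.behaviors is not None:
        for b, group in enumerate(family.behaviors):
            for i in group:
                behavior_of[i] = b
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["network", "mse", "size", "behavior"])
        for i, net in enumerate(family.networks):
            w.writerow([i, f"{family.fitness:.6g}", net.size, behavior_of.get(i, "")])


def write_network_sif(net: BooleanNetwork, path) -> None:
    """Extended SIF: 2-literal clauses go through an AND pseudo-node."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, c in enumerate(net.sorted_clauses()):
            if len(c.literals) == 1:
                (n, s), = c.literals
                fh.write(f"{n}\t{s:d}\t{c.target}\n")
            else:
                gate = f"and_{i}"
                for n, s in c.literals:
                    fh.write(f"{n}\t{s:d}\t{gate}\n")
                fh.write(f"{gate}\t1\t{c.target}\n")
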