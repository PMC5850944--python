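"""Synthetic PKNs, planted class models, and patient tables.

The generator emulates the structure the pipeline assumes: a layered acyclic
signed network (stimuli -> inhibitors -> readouts), two planted Boolean
networks drawn from its AND-gate hypergraph that differ in a fixed number of
clauses (the class-specific mechanisms), and per-patient continuous
measurements: input bits plus Gaussian noise, readout fixpoints plus Gaussian
noise clipped to [0,1], all affine-mapped onto a positive RPPA-like scale so
the binarization and normalization stages are exercised non-trivially.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import learning, pkn as pkn_mod, preprocessing
from .learning import BooleanNetwork, Experiment, SynchronousEngine
from .pkn import PKN, Clause, HyperGraph, SignedEdge, expand_hypergraph
from .preprocessing import CR, PR, PatientDataset

logger = logging.getLogger(__name__)

#: affine map from model scale [0,1]-ish onto an RPPA-like positive range
RAW_OFFSET = 400.0
RAW_SCALE = 1800.0


@dataclass
class SynthConfig:
    n_stimuli: int = 3
    n_inhibitors: int = 3
    n_readouts: int = 2
    n_patients_per_class: int = 12
    n_holdout_per_class: int = 0
    clause_density: float = 0.5
    divergence: int = 2  # clauses differing between the class models
    noise_sd: float = 0.0
    input_bit_prob: float = 0.5
    seed: int = 0
    max_parents: int = 2
    activation_prob: float = 0.7
    informative_patients: bool = True
    feedback_edges: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.input_bit_prob < 1.0:
            raise ValueError("input_bit_prob must lie in (0,1)")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")


@dataclass
class SynthBundle:
    pkn: PKN
    hypergraph: HyperGraph
    truth_cr: BooleanNetwork
    truth_pr: BooleanNetwork
    data: PatientDataset
    holdout: PatientDataset | None = None
    config: SynthConfig | None = None


# ---------------------------------------------------------------------------
# topology and planted models
# ---------------------------------------------------------------------------

def _build_pkn(cfg: SynthConfig, rng: np.random.Generator) -> PKN:
    stimuli = [f"S{i+1}" for i in range(cfg.n_stimuli)]
    inhibitors = [f"I{i+1}" for i in range(cfg.n_inhibitors)]
    readouts = [f"R{i+1}" for i in range(cfg.n_readouts)]
    edges: list[SignedEdge] = []
    seen: set[tuple[str, str]] = set()
    indeg: dict[str, int] = {}

    def add(src: str, tgt: str, force: bool = False) -> bool:
        # max_parents is a hard in-degree cap (keeps the clause count, hence
        # the exhaustive search space, bounded); force only as a last resort
        if (src, tgt) in seen or src == tgt:
            return False
        if not force and indeg.get(tgt, 0) >= cfg.max_parents:
            return False
        sign = 1 if rng.random() < cfg.activation_prob else -1
        edges.append(SignedEdge(src, tgt, sign))
        seen.add((src, tgt))
        indeg[tgt] = indeg.get(tgt, 0) + 1
        return True

    def pick_parents(node: str, pool: list[str], n_par: int) -> None:
        # prefer sources that do not yet regulate anything, so that the
        # later "every input regulates something" repair stays within the
        # in-degree cap
        with_out = {e.source for e in edges}
        order = sorted(
            rng.permutation(pool).tolist(), key=lambda s: s in with_out
        )
        added = 0
        for src in order:
            if added >= n_par:
                break
            if add(str(src), node):
                added += 1

    for i, node in enumerate(inhibitors):
        pool = stimuli + inhibitors[:i]
        pick_parents(node, pool, int(rng.integers(1, min(cfg.max_parents, len(pool)) + 1)))
    upstream = stimuli + inhibitors
    for node in readouts:
        pick_parents(node, upstream, int(rng.integers(1, min(cfg.max_parents, len(upstream)) + 1)))
    # every stimulus must regulate something; every inhibitor must be used
    def ensure_outgoing(node: str, sinks: list[str]) -> None:
        if node in {e.source for e in edges}:
            return
        for tgt in rng.permutation(sinks):
            if add(node, str(tgt)):
                return
        for tgt in rng.permutation(sinks):  # all sinks saturated
            if add(node, str(tgt), force=True):
                return

    sinks = inhibitors + readouts if inhibitors else readouts
    for s in stimuli:
        ensure_outgoing(s, sinks)
    for i_node in inhibitors:
        ensure_outgoing(i_node, readouts)
    for _ in range(cfg.feedback_edges):  # optional cycles for robustness tests
        if len(inhibitors) >= 2:
            a, b = rng.choice(inhibitors, size=2, replace=False)
            add(str(b), str(a))
    return PKN(edges)


def _sample_network(
    hg: HyperGraph, cfg: SynthConfig, rng: np.random.Generator
) -> BooleanNetwork:
    chosen: set[Clause] = set()
    targets = sorted({c.target for c in hg.clauses})
    for t in targets:
        cands = hg.clauses_for(t)
        picks = [c for c in cands if rng.random() < cfg.clause_density]
        if not picks:  # every regulated node gets at least one mechanism
            picks = [cands[int(rng.integers(len(cands)))]]
        chosen.update(picks)
    return BooleanNetwork(frozenset(chosen))


def _readout_signature(
    net: BooleanNetwork, pkn: PKN, patterns: list[dict[str, int]]
) -> tuple:
    engine = SynchronousEngine(pkn.nodes, net.sorted_clauses(), patterns)
    states, osc = engine.run(range(net.size))
    stable = engine.full & ~osc
    return tuple(states[engine.index[r]] & stable for r in pkn.readouts)


def _input_patterns(pkn: PKN, rng: np.random.Generator, cap: int = 12):
    inputs = sorted(set(pkn.stimuli) | set(pkn.inhibitors))
    n = len(inputs)
    if n <= cap:
        return [
            {v: (p >> i) & 1 for i, v in enumerate(inputs)} for p in range(1 << n)
        ]
    bits = rng.integers(0, 2, size=(256, n))
    return [dict(zip(inputs, map(int, row))) for row in bits]


def _diverge(
    truth_cr: BooleanNetwork,
    hg: HyperGraph,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> BooleanNetwork:
    """Toggle exactly ``divergence`` clauses so the readout behavior differs."""
    if cfg.divergence == 0:
        return truth_cr
    if cfg.divergence > len(hg.clauses):
        raise ValueError(
            f"divergence {cfg.divergence} exceeds the {len(hg.clauses)} candidate clauses"
        )
    patterns = _input_patterns(hg.pkn, rng)
    sig_cr = _readout_signature(truth_cr, hg.pkn, patterns)
    for _ in range(200):
        toggles = rng.choice(len(hg.clauses), size=cfg.divergence, replace=False)
        clauses = set(truth_cr.clauses)
        for t in toggles:
            c = hg.clauses[int(t)]
            clauses.symmetric_difference_update({c})
        cand = BooleanNetwork(frozenset(clauses))
        if _readout_signature(cand, hg.pkn, patterns) != sig_cr:
            return cand
    raise ValueError(
        "could not find a divergent model with different readout behavior; "
        "increase divergence or clause_density"
    )


# ---------------------------------------------------------------------------
# patient sampling
# ---------------------------------------------------------------------------

def _truth_readouts(net: BooleanNetwork, pkn: PKN, bits: dict[str, int]) -> dict[str, int]:
    fp = learning.fixpoint(net, bits, nodes=pkn.nodes)
    return {r: fp[r] for r in pkn.readouts}


def _sample_patients(
    pkn: PKN,
    truths: dict[str, BooleanNetwork],
    cfg: SynthConfig,
    n_per_class: int,
    rng: np.random.Generator,
    prefix: str = "",
) -> PatientDataset:
    inputs = sorted(set(pkn.stimuli) | set(pkn.inhibitors))
    readouts = list(pkn.readouts)
    informative = cfg.informative_patients and cfg.divergence > 0
    rows, ids, labels = [], [], []
    for klass in (CR, PR):
        for p in range(n_per_class):
            for attempt in range(1000):
                bits = {
                    v: int(rng.random() < cfg.input_bit_prob) for v in inputs
                }
                if not informative:
                    break
                if _truth_readouts(truths[CR], pkn, bits) != _truth_readouts(
                    truths[PR], pkn, bits
                ):
                    break
            else:
                logger.warning(
                    "no class-informative input pattern found after 1000 draws; "
                    "keeping an uninformative patient"
                )
            truth = _truth_readouts(truths[klass], pkn, bits)
            in_vals = {
                v: bits[v] + rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else float(bits[v])
                for v in inputs
            }
            out_vals = {
                r: float(np.clip(truth[r] + rng.normal(0.0, cfg.noise_sd), 0.0, 1.0))
                if cfg.noise_sd
                else float(truth[r])
                for r in readouts
            }
            row = {v: RAW_OFFSET + RAW_SCALE * in_vals[v] for v in inputs}
            row.update({r: RAW_OFFSET + RAW_SCALE * out_vals[r] for r in readouts})
            rows.append(row)
            ids.append(f"{prefix}{klass}{p+1:03d}")
            labels.append(klass)
    values = pd.DataFrame(rows, index=ids, columns=inputs + readouts)
    return PatientDataset(values=values, labels=pd.Series(labels, index=ids))


def generate(config: SynthConfig) -> SynthBundle:
    """Build PKN, planted class models, and (optionally held-out) patients."""
    rng = np.random.default_rng(config.seed)
    pkn = _build_pkn(config, rng)
    if config.feedback_edges == 0:
        import networkx as nx

        assert nx.is_directed_acyclic_graph(pkn.to_networkx())
    hg = expand_hypergraph(pkn)
    truth_cr = _sample_network(hg, config, rng)
    truth_pr = _diverge(truth_cr, hg, config, rng)
    truths = {CR: truth_cr, PR: truth_pr}
    data = _sample_patients(pkn, truths, config, config.n_patients_per_class, rng)
    holdout = None
    if config.n_holdout_per_class:
        holdout = _sample_patients(
            pkn, truths, config, config.n_holdout_per_class, rng, prefix="T"
        )
    return SynthBundle(
        pkn=pkn,
        hypergraph=hg,
        truth_cr=truth_cr,
        truth_pr=truth_pr,
        data=data,
        holdout=holdout,
        config=config,
    )


def exhaustive_experiments(
    pkn: PKN,
    net: BooleanNetwork,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    max_inputs: int = 16,
) -> list[Experiment]:
    """One noise-free (or noisy) experiment per input clamping of the PKN."""
    inputs = sorted(set(pkn.stimuli) | set(pkn.inhibitors))
    if len(inputs) > max_inputs:
        raise ValueError(f"{len(inputs)} inputs exceed the enumeration cap {max_inputs}")
    exps = []
    for pattern in range(1 << len(inputs)):
        bits = {v: (pattern >> i) & 1 for i, v in enumerate(inputs)}
        truth = _truth_readouts(net, pkn, bits)
        obs = {}
        for r, v in truth.items():
            val = float(v)
            if noise_sd and rng is not None:
                val = float(np.clip(val + rng.normal(0.0, noise_sd), 0.0, 1.0))
            obs[r] = val
        exps.append(Experiment(clamped=bits, observed=obs))
    return exps


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

PRESETS: dict[str, SynthConfig] = {
    "tiny": SynthConfig(
        n_stimuli=3, n_inhibitors=3, n_readouts=2,
        n_patients_per_class=8, n_holdout_per_class=8,
        divergence=2, noise_sd=0.1,
    ),
    "small": SynthConfig(
        n_stimuli=5, n_inhibitors=8, n_readouts=4,
        n_patients_per_class=30, n_holdout_per_class=30,
        divergence=3, noise_sd=0.1,
    ),
    "paper-shaped": SynthConfig(
        n_stimuli=17, n_inhibitors=62, n_readouts=23,
        n_patients_per_class=96, n_holdout_per_class=50,
        divergence=4, noise_sd=0.1,
    ),
}


def make_fixture(name: str, outdir, seed: int = 0) -> Path:
    """Write SIF + patient CSV + planted-model JSON for a named preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = SynthConfig(**{**asdict(PRESETS[name]), "seed": seed})
    bundle = generate(cfg)
    data = bundle.data
    if name == "paper-shaped":  # 96 CR + 95 PR patients
        keep = [i for i in data.values.index if i != f"{PR}096"]
        data = PatientDataset(values=data.values.loc[keep], labels=data.labels.loc[keep])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pkn_mod.write_sif(bundle.pkn, outdir / "pkn.sif")
    preprocessing.write_patient_table(data, outdir / "patients.csv")
    if bundle.holdout is not None:
        preprocessing.write_patient_table(bundle.holdout, outdir / "patients_test.csv")
    for label, net in (("cr", bundle.truth_cr), ("pr", bundle.truth_pr)):
        with open(outdir / f"truth_{label}.json", "w", encoding="utf-8") as fh:
            json.dump(net.to_json_obj(), fh, indent=1, sort_keys=True)
            fh.write("\n")
    with open(outdir / "meta.json", "w", encoding="utf-8") as fh:
        json.dump({"preset": name, "config": asdict(cfg)}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir
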