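"""Reference evaluation protocols on synthetic studies.

Two standard experiments used for validating the pipeline end to end:

* planted-model recovery — learn each class family from noise-free
  experiments covering every input clamping and check that the planted
  network's input-output behavior is recovered with zero fitting error and
  that held-out patients are classified perfectly;
* noise sweep — repeat the experiment at increasing measurement noise
  (applied to both the learning observations and the held-out patient
  table) and track the mean balanced accuracy across seeds.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import classification, learning, preprocessing, synth
from .classification import AccuracyReport
from .learning import BNFamily
from .preprocessing import CR, PR
from .synth import SynthBundle, SynthConfig

logger = logging.getLogger(__name__)


def learn_from_exhaustive(
    bundle: SynthBundle,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    **learn_kw,
) -> tuple[BNFamily, BNFamily]:
    """Learn both class families from all-pattern experiments of the truths."""
    fams = []
    for net in (bundle.truth_cr, bundle.truth_pr):
        exps = synth.exhaustive_experiments(bundle.pkn, net, noise_sd=noise_sd, rng=rng)
        fam = learning.learn(bundle.hypergraph, exps, **learn_kw)
        learning.classify_behaviors(fam)
        fams.append(fam)
    return fams[0], fams[1]


def behavior_recovered(family: BNFamily, planted, bundle: SynthBundle) -> bool:
    """Does the family contain a network I/O-equivalent to the planted one?"""
    probe = BNFamily(
        networks=[planted] + list(family.networks),
        fitness=family.fitness,
        size=family.size,
        nodes=tuple(bundle.pkn.nodes),
        clamp_nodes=family.clamp_nodes,
        readouts=family.readouts,
    )
    groups = learning.classify_behaviors(probe)
    planted_group = next(g for g in groups if 0 in g)
    return len(planted_group) > 1


def classify_holdout(
    cr_family: BNFamily,
    pr_family: BNFamily,
    holdout: preprocessing.PatientDataset,
    method: int = 1,
    **kwargs,
) -> AccuracyReport:
    """Preprocess a held-out patient table and score both families on it."""
    inputs = sorted(set(cr_family.clamp_nodes) | set(pr_family.clamp_nodes))
    readouts = sorted(set(cr_family.readouts) | set(pr_family.readouts))
    proc = preprocessing.preprocess(holdout, inputs, readouts)
    preds = [
        classification.classify_patient(
            cr_family,
            pr_family,
            proc.inputs.loc[p].to_dict(),
            proc.readouts.loc[p].to_dict(),
            patient=str(p),
            method=method,
            **kwargs,
        )
        for p in proc.inputs.index
    ]
    truth = {str(i): l for i, l in holdout.labels.items()}
    return classification.evaluate(preds, truth)


def planted_recovery(seed: int = 0, config: SynthConfig | None = None) -> dict:
    """One noise-free recovery experiment; returns the headline numbers."""
    cfg = config or SynthConfig(
        n_patients_per_class=10, n_holdout_per_class=10, divergence=2, noise_sd=0.0
    )
    cfg = dataclasses.replace(cfg, seed=seed, noise_sd=0.0)
    bundle = synth.generate(cfg)
    cr_fam, pr_fam = learn_from_exhaustive(bundle)
    report = classify_holdout(cr_fam, pr_fam, bundle.holdout)
    return {
        "balanced_accuracy": report.balanced,
        "mse_cr": cr_fam.fitness,
        "mse_pr": pr_fam.fitness,
        "recovered_cr": behavior_recovered(cr_fam, bundle.truth_cr, bundle),
        "recovered_pr": behavior_recovered(pr_fam, bundle.truth_pr, bundle),
        "n_networks_cr": len(cr_fam.networks),
        "n_networks_pr": len(pr_fam.networks),
    }


def noise_sweep(
    noise_levels=(0.0, 0.1, 0.3),
    n_seeds: int = 20,
    base_seed: int = 0,
    config: SynthConfig | None = None,
) -> dict[float, float]:
    """Mean balanced accuracy (percent) per noise level across seeds.

    At each level the same protocol runs: plant two divergent class models,
    learn families from all-pattern experiments whose readout observations
    carry the level's Gaussian noise, then classify a noisy held-out patient
    table through the standard binarize/normalize preprocessing.
    """
    cfg = config or SynthConfig(
        n_stimuli=3,
        n_inhibitors=2,
        n_readouts=2,
        n_patients_per_class=2,
        n_holdout_per_class=10,
        divergence=2,
    )
    means: dict[float, float] = {}
    for sd in noise_levels:
        accs = []
        for s in range(n_seeds):
            run_seed = (base_seed + 7919 * s) % (2**31 - 1)
            bundle = synth.generate(
                dataclasses.replace(cfg, seed=run_seed, noise_sd=sd)
            )
            rng = np.random.default_rng(run_seed + 1)
            cr_fam, pr_fam = learn_from_exhaustive(bundle, noise_sd=sd, rng=rng)
            report = classify_holdout(cr_fam, pr_fam, bundle.holdout)
            accs.append(report.balanced)
        means[float(sd)] = float(np.mean(accs))
    return means
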