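"""Patient classification by Boolean-network family fit, and accuracy metrics.

Method 1: predict each patient's readouts from both class families (clamping
the selected input proteins to the patient's binarized values), compute the
MSE of each family against the measured normalized readouts, and call the
class with the lower MSE.  Method 2 first drops patients whose readout
signals are not near-Boolean (no significant measure), at the cost of
leaving them unclassified.  The confidence score mse_PR / (mse_CR + mse_PR)
lies in [0,1]; 1 means complete confidence in remission (CR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import learning, pkn as pkn_mod, preprocessing, selection
from .learning import BNFamily
from .preprocessing import CR, PR, PatientDataset

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"


@dataclass
class Prediction:
    patient: str
    mse_cr: float
    mse_pr: float
    label: str  # CR | PR | unknown
    confidence: float  # in [0,1]; 1 = confident CR
    tie: bool = False


@dataclass
class AccuracyReport:
    """Per-class and balanced accuracy, in percent, with analyzed counts."""

    acc_cr: float
    acc_pr: float
    balanced: float
    n_cr: int
    n_pr: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "acc_cr": self.acc_cr,
            "acc_pr": self.acc_pr,
            "balanced": self.balanced,
            "n_cr": self.n_cr,
            "n_pr": self.n_pr,
            "n_excluded": self.n_excluded,
        }


def balanced_accuracy(acc_cr: float, acc_pr: float) -> float:
    """Unweighted mean of the two per-class accuracies."""
    return (acc_cr + acc_pr) / 2.0


def filter_significant(
    patient_readouts: dict[str, float],
    low: float = 0.25,
    high: float = 0.6,
    mode: str = "all",
) -> bool:
    """Keep a patient only if readout values are near-Boolean (v<low or v>high).

    ``mode="all"`` (default) requires every readout to be significant;
    ``"any"`` requires at least one.  Returns True to keep.
    """
    if not 0.0 <= low < high <= 1.0:
        raise ValueError("thresholds must satisfy 0 <= low < high <= 1")
    if mode not in ("all", "any"):
        raise ValueError(f"unknown mode {mode!r}")
    if not patient_readouts:
        logger.warning("filter_significant: empty readout map; dropping patient")
        return False
    sig = [(v < low or v > high) for v in patient_readouts.values()]
    return all(sig) if mode == "all" else any(sig)


def classify_patient(
    cr_family: BNFamily,
    pr_family: BNFamily,
    patient_inputs: dict[str, int],
    patient_readouts: dict[str, float],
    patient: str = "?",
    method: int = 1,
    low: float = 0.25,
    high: float = 0.6,
    sig_mode: str = "all",
) -> Prediction:
    """MSE-based class call for one patient (Method 1, or Method 2 with filter)."""
    if method not in (1, 2):
        raise ValueError("method must be 1 or 2")
    targets = sorted(set(cr_family.readouts) | set(pr_family.readouts))
    shared = [r for r in targets if r in patient_readouts]
    missing = [r for r in targets if r not in patient_readouts]
    if missing:
        logger.warning("patient %s: readouts %s unmeasured; excluded", patient, missing)
    if not shared:
        raise ValueError(f"patient {patient}: no overlapping readouts with the families")
    readout_map = {r: float(patient_readouts[r]) for r in shared}
    if method == 2 and not filter_significant(readout_map, low, high, sig_mode):
        return Prediction(patient, math.nan, math.nan, UNKNOWN, 0.5)

    def family_mse(family: BNFamily) -> float:
        clamps = {}
        for n in family.clamp_nodes:
            if n not in patient_inputs:
                raise ValueError(f"patient {patient}: missing input bit for {n}")
            clamps[n] = int(patient_inputs[n])
        preds = learning.predict(family, clamps, shared)
        return float(np.mean([(preds[r] - readout_map[r]) ** 2 for r in shared]))

    mse_cr = family_mse(cr_family)
    mse_pr = family_mse(pr_family)
    if mse_cr == 0.0 and mse_pr == 0.0:
        conf = 0.5
    else:
        conf = mse_pr / (mse_cr + mse_pr)
    if mse_cr < mse_pr:
        label, tie = CR, False
    elif mse_pr < mse_cr:
        label, tie = PR, False
    else:
        # tie: Method 2 abstains, Method 1 falls back to CR (majority class)
        tie = True
        label = UNKNOWN if method == 2 else CR
        logger.info("patient %s: MSE tie (%.6g)", patient, mse_cr)
    return Prediction(patient, mse_cr, mse_pr, label, conf, tie)


def evaluate(predictions: list[Prediction], truth: dict[str, str]) -> AccuracyReport:
    """Per-class accuracy over classified patients; balanced = their mean.

    Patients with an ``unknown`` prediction are excluded from denominators.
    A class with no classified patients yields NaN for that accuracy (and for
    the balanced accuracy).
    """
    counts = {CR: [0, 0], PR: [0, 0]}  # class -> [correct, classified]
    excluded = 0
    for p in predictions:
        if p.label == UNKNOWN:
            excluded += 1
            continue
        if p.patient not in truth:
            raise ValueError(f"no truth label for classified patient {p.patient}")
        t = truth[p.patient]
        counts[t][1] += 1
        if p.label == t:
            counts[t][0] += 1
    def pct(c):
        return 100.0 * c[0] / c[1] if c[1] else math.nan
    acc_cr, acc_pr = pct(counts[CR]), pct(counts[PR])
    bal = balanced_accuracy(acc_cr, acc_pr)
    return AccuracyReport(
        acc_cr=acc_cr,
        acc_pr=acc_pr,
        balanced=bal,
        n_cr=counts[CR][1],
        n_pr=counts[PR][1],
        n_excluded=excluded,
    )


class BNFamilyClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end estimator: preprocess, select, learn families, classify.

    Parameters
    ----------
    pkn : PKN
        Signed prior knowledge network constraining the model space.
    k : int or None
        Number of input proteins to select; None uses all measured inputs.
    max_gate_inputs : int
        AND-gate arity cap of the hypergraph expansion (1 or 2).
    binarize_scope, normalize_scope : {"global", "per-protein"}
        Preprocessing scopes (global pools all measurements, the default).
    fit_tolerance, size_tolerance : float, int
        Co-optimality tolerances of the family learner.
    method : {1, 2}
        Classification method; 2 abstains on patients without significant
        (near-Boolean) readout signals, using ``low``/``high``/``sig_mode``.
    max_clauses : int
        Exhaustive-search guard of the learner.

    Fitted attributes: ``binarizer_``, ``normalizer_``, ``selector_``,
    ``hypergraph_``, ``cr_family_``, ``pr_family_``, ``classes_``.
    """

    def __init__(
        self,
        pkn,
        k: int | None = None,
        max_gate_inputs: int = 2,
        binarize_scope: str = "global",
        normalize_scope: str = "global",
        fit_tolerance: float = 0.0,
        size_tolerance: int = 0,
        method: int = 1,
        low: float = 0.25,
        high: float = 0.6,
        sig_mode: str = "all",
        max_clauses: int = 20,
        random_state: int = 0,
    ):
        self.pkn = pkn
        self.k = k
        self.max_gate_inputs = max_gate_inputs
        self.binarize_scope = binarize_scope
        self.normalize_scope = normalize_scope
        self.fit_tolerance = fit_tolerance
        self.size_tolerance = size_tolerance
        self.method = method
        self.low = low
        self.high = high
        self.sig_mode = sig_mode
        self.max_clauses = max_clauses
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------
    def _measured_roles(self, columns) -> tuple[list[str], list[str]]:
        net = self.pkn
        inputs = [p for p in sorted(set(net.stimuli) | set(net.inhibitors)) if p in columns]
        readouts = [p for p in net.readouts if p in columns]
        ignored = [c for c in columns if c not in net.nodes]
        if ignored:
            logger.warning("proteins absent from the PKN ignored: %s", sorted(ignored))
        if not inputs or not readouts:
            raise ValueError("data must measure at least one input and one readout protein")
        return inputs, readouts

    def fit(self, X: pd.DataFrame, y=None) -> "BNFamilyClassifier":
        """Fit on a patients x proteins table; ``y`` holds CR/PR labels."""
        if isinstance(X, PatientDataset):
            data = X
        else:
            X = pd.DataFrame(X)
            if y is None:
                raise ValueError("y (CR/PR labels) is required")
            data = PatientDataset(values=X, labels=pd.Series(list(y), index=X.index))
        inputs, readouts = self._measured_roles(data.values.columns)
        self.binarizer_ = preprocessing.InputBinarizer(
            scope=self.binarize_scope, random_state=self.random_state
        ).fit(data.values[inputs])
        self.normalizer_ = preprocessing.ReadoutNormalizer(
            scope=self.normalize_scope
        ).fit(data.values[readouts])
        proc = preprocessing.ProcessedDataset(
            inputs=self.binarizer_.transform(data.values[inputs]),
            readouts=self.normalizer_.transform(data.values[readouts]),
            labels=data.labels,
        )
        self.selector_ = selection.CoupleSelector(k=self.k).fit(proc)
        if self.selector_.selection_ is None:
            raise ValueError("no CR-PR couple achievable; cannot build experiments")
        red_cr, red_pr = selection.build_reduced_datasets(proc, self.selector_.selection_)
        self.hypergraph_ = pkn_mod.expand_hypergraph(self.pkn, self.max_gate_inputs)
        learner = dict(
            fit_tolerance=self.fit_tolerance,
            size_tolerance=self.size_tolerance,
            max_clauses=self.max_clauses,
        )
        self.cr_family_ = learning.learn(self.hypergraph_, red_cr.to_experiments(), **learner)
        self.pr_family_ = learning.learn(self.hypergraph_, red_pr.to_experiments(), **learner)
        learning.classify_behaviors(self.cr_family_)
        learning.classify_behaviors(self.pr_family_)
        self.processed_ = proc
        self.classes_ = np.array([CR, PR])
        return self

    def predict_detailed(self, X: pd.DataFrame) -> list[Prediction]:
        if isinstance(X, PatientDataset):
            X = X.values
        X = pd.DataFrame(X)
        bits = self.binarizer_.transform(X[self.binarizer_.columns_])
        norm = self.normalizer_.transform(X[self.normalizer_.columns_])
        preds = []
        for patient in X.index:
            preds.append(
                classify_patient(
                    self.cr_family_,
                    self.pr_family_,
                    bits.loc[patient].to_dict(),
                    norm.loc[patient].to_dict(),
                    patient=str(patient),
                    method=self.method,
                    low=self.low,
                    high=self.high,
                    sig_mode=self.sig_mode,
                )
            )
        return preds

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.array([p.label for p in self.predict_detailed(X)])

    def predict_confidence(self, X: pd.DataFrame) -> np.ndarray:
        """Confidence in [0,1] that each patient achieves complete remission."""
        return np.array([p.confidence for p in self.predict_detailed(X)])

    def score(self, X, y) -> float:
        """Balanced accuracy (fraction, not percent) over classified patients."""
        preds = self.predict_detailed(X)
        X = X.values if isinstance(X, PatientDataset) else pd.DataFrame(X)
        truth = dict(zip((str(i) for i in X.index), y))
        report = evaluate(preds, truth)
        return report.balanced / 100.0
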