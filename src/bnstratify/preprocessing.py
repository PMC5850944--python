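"""Patient-table containers and the binarize/normalize preprocessing stage.

Continuous protein measurements are split into *input* proteins (stimuli and
inhibitors), discretized to {0,1} by a two-cluster k-means, and *readout*
proteins, min-max normalized into [0,1].  A measurement's bit is the bit of
its cluster: centres are rescaled to the data's min-max range and a centre c
maps to 1 when (1 - c) <= 0.5, i.e. c >= 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

CR = "CR"
PR = "PR"
LABELS = (CR, PR)


@dataclass
class PatientDataset:
    """Patients x proteins matrix of continuous measurements with class labels."""

    values: pd.DataFrame  # index: patient ids, columns: protein ids
    labels: pd.Series  # patient id -> "CR" | "PR"

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"missing class label for patients: {missing}")
        bad = set(self.labels.unique()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("patient table contains missing or non-finite values")

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProcessedDataset:
    """Binarized inputs (a_ij in {0,1}) and normalized readouts (r_ij in [0,1])."""

    inputs: pd.DataFrame
    readouts: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.inputs.isin([0, 1]).all().all():
            raise ValueError("inputs must be strictly binary")
        arr = self.readouts.to_numpy(dtype=float)
        if arr.size and (arr.min() < -1e-12 or arr.max() > 1 + 1e-12):
            raise ValueError("readouts must lie in [0, 1]")

    @property
    def patients(self) -> list[str]:
        return list(self.inputs.index)


def load_patient_table(path, sep: str | None = None) -> PatientDataset:
    """Read a CSV/TSV patient table: first column patient id, a ``class``
    column with CR/PR, remaining columns protein measurements."""
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    if "class" not in df.columns:
        raise ValueError(f"{path}: missing required 'class' column")
    labels = df["class"].astype(str)
    values = df.drop(columns=["class"]).astype(float)
    return PatientDataset(values=values, labels=labels)


def write_patient_table(data: PatientDataset, path) -> None:
    out = data.values.copy()
    out.insert(0, "class", data.labels)
    out.to_csv(path, index_label="patient")


# ---------------------------------------------------------------------------
# exact one-dimensional 2-means
# ---------------------------------------------------------------------------

def kmeans_1d_two(values: np.ndarray) -> tuple[float, float, float] | None:
    """Exact two-cluster k-means on a 1-D sample.

    An optimal 2-means partition of sorted reals is a prefix/suffix split, so
    scanning the n-1 split points with prefix sums finds the global optimum
    deterministically.  Returns ``(low_centre, high_centre, boundary)`` where
    ``boundary`` is the midpoint of the two centres (nearest-centre
    assignment), or ``None`` when all values coincide (degenerate).
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return None
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    ks = np.arange(1, n)  # size of the left cluster
    left_sum, left_sq = csum[:-1], csq[:-1]
    right_sum, right_sq = csum[-1] - left_sum, csq[-1] - left_sq
    sse = (left_sq - left_sum**2 / ks) + (right_sq - right_sum**2 / (n - ks))
    # forbid splits between equal values (both sides must be non-empty sets
    # of distinct positions; equal neighbours give identical partitions)
    valid = x[1:] > x[:-1]
    sse = np.where(valid, sse, np.inf)
    k = int(np.argmin(sse)) + 1
    lo = float(left_sum[k - 1] / k)
    hi = float((csum[-1] - left_sum[k - 1]) / (n - k))
    boundary = (lo + hi) / 2.0
    return lo, hi, float(boundary)


class InputBinarizer(BaseEstimator, TransformerMixin):
    """Discretize input-protein measurements to {0,1} via 2-means clustering.

    Parameters
    ----------
    scope : {"global", "per-protein"}
        ``global`` (default) pools every input measurement into one 1-D
        clustering; ``per-protein`` clusters each column separately.
    random_state : int
        Accepted for scikit-learn compatibility; the 1-D solver is exact and
        deterministic, so the seed has no effect.
    """

    def __init__(self, scope: str = "global", random_state: int = 0):
        self.scope = scope
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "InputBinarizer":
        if self.scope not in ("global", "per-protein"):
            raise ValueError(f"unknown scope {self.scope!r}")
        X = pd.DataFrame(X)
        if X.shape[1] == 0:
            raise ValueError("no input proteins to binarize")
        self.columns_ = list(X.columns)
        self.solutions_: dict[str, tuple[float, float, float] | None] = {}
        if self.scope == "global":
            sol = self._solve(X.to_numpy(dtype=float).ravel(), "all inputs")
            for c in self.columns_:
                self.solutions_[c] = sol
        else:
            for c in self.columns_:
                self.solutions_[c] = self._solve(
                    X[c].to_numpy(dtype=float), f"protein {c}"
                )
        return self

    @staticmethod
    def _solve(values: np.ndarray, what: str):
        sol = kmeans_1d_two(values)
        if sol is None:
            logger.warning("constant measurements for %s: binarized to all zeros", what)
            return None
        lo, hi, boundary = sol
        vmin, vmax = float(np.min(values)), float(np.max(values))
        # rescale centres onto [0,1] over the clustered range, then apply the
        # threshold: bit(c) = 1 iff (1 - c_scaled) <= 0.5
        lo_s = (lo - vmin) / (vmax - vmin)
        hi_s = (hi - vmin) / (vmax - vmin)
        bit_lo = int((1.0 - lo_s) <= 0.5)
        bit_hi = int((1.0 - hi_s) <= 0.5)
        return boundary, bit_lo, bit_hi

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise ValueError(f"input proteins absent from data: {missing}")
        out = {}
        for c in self.columns_:
            sol = self.solutions_[c]
            col = X[c].to_numpy(dtype=float)
            if sol is None:
                out[c] = np.zeros(len(col), dtype=int)
            else:
                boundary, bit_lo, bit_hi = sol
                out[c] = np.where(col > boundary, bit_hi, bit_lo).astype(int)
        return pd.DataFrame(out, index=X.index, columns=self.columns_)


class ReadoutNormalizer(BaseEstimator, TransformerMixin):
    """Min-max normalize readout measurements into [0,1].

    ``scope="global"`` (default) uses one (min, max) over every readout of
    every patient; ``per-protein`` normalizes each column separately.  Values
    of new data falling outside the fitted range are clipped to [0,1].
    """

    def __init__(self, scope: str = "global"):
        self.scope = scope

    def fit(self, X: pd.DataFrame, y=None) -> "ReadoutNormalizer":
        if self.scope not in ("global", "per-protein"):
            raise ValueError(f"unknown scope {self.scope!r}")
        X = pd.DataFrame(X)
        if X.shape[1] == 0:
            raise ValueError("no readout proteins to normalize")
        self.columns_ = list(X.columns)
        arr = X.to_numpy(dtype=float)
        if self.scope == "global":
            lo, hi = float(arr.min()), float(arr.max())
            if hi <= lo:
                raise ValueError("degenerate readout range (max == min)")
            self.min_ = pd.Series(lo, index=self.columns_)
            self.max_ = pd.Series(hi, index=self.columns_)
        else:
            lo = X.min(axis=0)
            hi = X.max(axis=0)
            if (hi <= lo).any():
                bad = list(hi.index[hi <= lo])
                raise ValueError(f"degenerate readout range for: {bad}")
            self.min_, self.max_ = lo.astype(float), hi.astype(float)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)[self.columns_]
        norm = (X - self.min_) / (self.max_ - self.min_)
        return norm.clip(0.0, 1.0)


# ---------------------------------------------------------------------------
# functional wrappers and dataset plumbing
# ---------------------------------------------------------------------------

def binarize_inputs(
    data: PatientDataset,
    input_proteins: list[str],
    scope: str = "global",
    seed: int = 0,
) -> pd.DataFrame:
    """Binarize the designated input-protein columns of a patient table."""
    if not input_proteins:
        raise ValueError("empty input protein list")
    missing = [p for p in input_proteins if p not in data.values.columns]
    if missing:
        raise ValueError(f"input proteins absent from data: {missing}")
    binarizer = InputBinarizer(scope=scope, random_state=seed)
    return binarizer.fit_transform(data.values[list(input_proteins)])


def normalize_readouts(
    data: PatientDataset, readout_proteins: list[str], scope: str = "global"
) -> pd.DataFrame:
    """Min-max normalize the designated readout columns into [0,1]."""
    if not readout_proteins:
        raise ValueError("empty readout protein list")
    missing = [p for p in readout_proteins if p not in data.values.columns]
    if missing:
        raise ValueError(f"readout proteins absent from data: {missing}")
    normalizer = ReadoutNormalizer(scope=scope)
    return normalizer.fit_transform(data.values[list(readout_proteins)])


def preprocess(
    data: PatientDataset,
    input_proteins: list[str],
    readout_proteins: list[str],
    binarize_scope: str = "global",
    normalize_scope: str = "global",
    seed: int = 0,
) -> ProcessedDataset:
    return ProcessedDataset(
        inputs=binarize_inputs(data, input_proteins, binarize_scope, seed),
        readouts=normalize_readouts(data, readout_proteins, normalize_scope),
        labels=data.labels.copy(),
    )


def split_by_class(proc: ProcessedDataset) -> tuple[ProcessedDataset, ProcessedDataset]:
    """Partition rows into the CR and PR datasets (column order preserved)."""
    out = []
    for label in LABELS:
        mask = proc.labels == label
        if not mask.any():
            raise ValueError(f"no patients with class {label}")
        out.append(
            ProcessedDataset(
                inputs=proc.inputs.loc[mask],
                readouts=proc.readouts.loc[mask],
                labels=proc.labels.loc[mask],
            )
        )
    return out[0], out[1]


def write_midas(
    proc: ProcessedDataset,
    couples,
    klass: str,
    path,
    pseudo_time: int = 10,
) -> None:
    """Write couples as MIDAS-format perturbation experiments.

    One row per couple: TR: columns carry the couple's shared input bits,
    DA:ALL the single pseudo-time, DV: columns the readouts of the couple's
    ``klass``-side patient.
    """
    if klass not in LABELS:
        raise ValueError(f"class must be CR or PR, got {klass!r}")
    header = (
        ["TR:patient:CellLine"]
        + [f"TR:{p}" for p in proc.inputs.columns]
        + ["DA:ALL"]
        + [f"DV:{r}" for r in proc.readouts.columns]
    )
    rows = []
    for c in couples:
        patient = c.cr_patient if klass == CR else c.pr_patient
        if patient not in proc.inputs.index:
            raise ValueError(f"couple references unknown patient {patient!r}")
        bits = proc.inputs.loc[patient]
        obs = proc.readouts.loc[patient]
        rows.append([1] + [int(b) for b in bits] + [pseudo_time] + [float(v) for v in obs])
    if not rows:
        logger.warning("write_midas: no couples; writing header-only file")
    df = pd.DataFrame(rows, columns=header)
    df.to_csv(path, index=False)


def read_midas(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a MIDAS CSV back into (input-bit, readout-value) frames."""
    df = pd.read_csv(path)
    tr = [c for c in df.columns if c.startswith("TR:") and not c.endswith("CellLine")]
    dv = [c for c in df.columns if c.startswith("DV:")]
    inputs = df[tr].rename(columns=lambda c: c[3:]).astype(int)
    readouts = df[dv].rename(columns=lambda c: c[3:]).astype(float)
    return inputs, readouts
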