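"""End-to-end orchestration: preprocess -> select -> learn -> classify.

Every stage writes its artifacts under the output directory and the run ends
with a ``manifest.json`` listing seed, package versions, and a SHA-256 hash
per artifact, so identical configurations produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classification, learning, pkn as pkn_mod, preprocessing, selection
from .preprocessing import CR, PR

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, last_artifact: str | None):
        self.stage = stage
        self.last_artifact = last_artifact
        msg = f"pipeline failed at stage {stage!r}: {cause}"
        if last_artifact:
            msg += f" (last good artifact: {last_artifact})"
        super().__init__(msg)


@dataclass
class PipelineConfig:
    pkn: str = ""
    patients: str = ""
    outdir: str = "run"
    test_patients: str | None = None
    sif_dialect: str = "numeric"
    k: int | None = None
    binarize_scope: str = "global"
    normalize_scope: str = "global"
    max_gate_inputs: int = 2
    fit_tolerance: float = 0.0
    size_tolerance: int = 0
    max_clauses: int = 20
    method: int = 1
    low: float = 0.25
    high: float = 0.6
    sig_mode: str = "all"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all four stages; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stages: list[str] = []
    last: str | None = None

    def emit(name: str, writer) -> None:
        nonlocal last
        path = outdir / name
        writer(path)
        artifacts[name] = _sha256(path)
        last = name

    # -- stage 1: preprocess ------------------------------------------------
    stage = "preprocess"
    try:
        net = pkn_mod.read_sif(config.pkn, dialect=config.sif_dialect)
        data = preprocessing.load_patient_table(config.patients)
        inputs = [
            p for p in sorted(set(net.stimuli) | set(net.inhibitors))
            if p in data.values.columns
        ]
        readouts = [p for p in net.readouts if p in data.values.columns]
        if not inputs or not readouts:
            raise ValueError("data must measure at least one input and one readout")
        binarizer = preprocessing.InputBinarizer(
            scope=config.binarize_scope, random_state=config.seed
        ).fit(data.values[inputs])
        normalizer = preprocessing.ReadoutNormalizer(scope=config.normalize_scope).fit(
            data.values[readouts]
        )
        proc = preprocessing.ProcessedDataset(
            inputs=binarizer.transform(data.values[inputs]),
            readouts=normalizer.transform(data.values[readouts]),
            labels=data.labels,
        )
        emit("inputs_binarized.csv", lambda p: proc.inputs.to_csv(p, index_label="patient"))
        emit("readouts_normalized.csv", lambda p: proc.readouts.to_csv(p, index_label="patient"))
        stages.append(stage)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc, last) from exc

    # -- stage 2: select ----------------------------------------------------
    stage = "select"
    try:
        k = config.k if config.k is not None else len(inputs)
        results = selection.select_proteins(proc, k=k)
        if not results:
            raise ValueError("no couple achievable at this k")
        sel = results[0]
        sel_obj = {
            "k": sel.k,
            "proteins": list(sel.proteins),
            "couples": [[c.cr_patient, c.pr_patient] for c in sel.couples],
            "n_couples": len(sel.couples),
            "affinity_count": sel.affinity_count,
            "readout_gap": sel.readout_gap,
            "n_co_optimal_selections": len(results),
        }
        emit(
            "selection.json",
            lambda p: p.write_text(json.dumps(sel_obj, indent=1, sort_keys=True) + "\n"),
        )
        red_cr, red_pr = selection.build_reduced_datasets(proc, sel)
        for name, red in (("reduced_cr.csv", red_cr), ("reduced_pr.csv", red_pr)):
            frame = pd.concat([red.inputs, red.readouts], axis=1)
            emit(name, lambda p, f=frame: f.to_csv(p, index_label="couple"))
        stages.append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc, last) from exc

    # -- stage 3: learn -----------------------------------------------------
    stage = "learn"
    try:
        hg = pkn_mod.expand_hypergraph(net, config.max_gate_inputs)
        families = {}
        for label, red in ((CR, red_cr), (PR, red_pr)):
            fam = learning.learn(
                hg,
                red.to_experiments(),
                fit_tolerance=config.fit_tolerance,
                size_tolerance=config.size_tolerance,
                max_clauses=config.max_clauses,
            )
            learning.classify_behaviors(fam)
            families[label] = fam
            low = label.lower()
            emit(f"family_{low}.json", lambda p, f=fam: learning.write_family_json(f, p))
            emit(f"frequencies_{low}.csv", lambda p, f=fam: learning.write_frequency_csv(f, p))
            emit(f"family_report_{low}.csv", lambda p, f=fam: learning.write_family_report_csv(f, p))
            emit(
                f"union_{low}.sif",
                lambda p, f=fam: learning.write_network_sif(learning.union_network(f), p),
            )
        stages.append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc, last) from exc

    # -- stage 4: classify --------------------------------------------------
    stage = "classify"
    try:
        if config.test_patients:
            target = preprocessing.load_patient_table(config.test_patients)
        else:
            target = data  # learning-dataset accuracy
        bits = binarizer.transform(target.values[inputs])
        norm = normalizer.transform(target.values[readouts])
        preds = []
        for patient in target.values.index:
            preds.append(
                classification.classify_patient(
                    families[CR],
                    families[PR],
                    bits.loc[patient].to_dict(),
                    norm.loc[patient].to_dict(),
                    patient=str(patient),
                    method=config.method,
                    low=config.low,
                    high=config.high,
                    sig_mode=config.sig_mode,
                )
            )
        pred_df = pd.DataFrame(
            [
                {
                    "patient": p.patient,
                    "mse_cr": p.mse_cr,
                    "mse_pr": p.mse_pr,
                    "confidence": p.confidence,
                    "label": p.label,
                }
                for p in preds
            ]
        )
        emit("predictions.csv", lambda p: pred_df.to_csv(p, index=False))
        truth = {str(i): l for i, l in target.labels.items()}
        report = classification.evaluate(preds, truth)
        emit(
            "accuracy.json",
            lambda p: p.write_text(
                json.dumps(
                    {k: (None if isinstance(v, float) and math.isnan(v) else v)
                     for k, v in report.to_dict().items()},
                    indent=1,
                    sort_keys=True,
                )
                + "\n"
            ),
        )
        stages.append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc, last) from exc

    import bnstratify

    manifest = {
        "stages": stages,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "versions": {"bnstratify": bnstratify.__version__},
        "search_space": pkn_mod.format_search_space(hg),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest


def report(outdir) -> str:
    """Human-readable summary of a completed run (learn + accuracy tables)."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{outdir}: no manifest.json (incomplete or missing run)")
    manifest = json.loads(manifest_path.read_text())
    lines = [f"Run summary ({outdir})", f"  stages completed: {', '.join(manifest['stages'])}"]
    partial = len(manifest["stages"]) < 4
    if partial:
        lines.append("  WARNING: incomplete run; partial report")
    lines.append("")
    lines.append("Learned families")
    lines.append(f"  search space: {manifest.get('search_space', '?')} candidate networks")
    for label in (CR, PR):
        path = outdir / f"family_{label.lower()}.json"
        if not path.exists():
            continue
        fam = learning.read_family_json(path)
        n_behaviors = len(fam.behaviors) if fam.behaviors else 1
        lines.append(
            f"  {label}: MSE={fam.fitness:.4g}  size={fam.size}  "
            f"networks={len(fam.networks)}  I/O={n_behaviors}"
        )
    acc_path = outdir / "accuracy.json"
    if acc_path.exists():
        acc = json.loads(acc_path.read_text())
        fmt = lambda v, n: (f"{v:.1f}% ({n})" if v is not None else f"NA ({n})")
        lines.append("")
        lines.append("Classification accuracy")
        lines.append(f"  CR: {fmt(acc['acc_cr'], acc['n_cr'])}")
        lines.append(f"  PR: {fmt(acc['acc_pr'], acc['n_pr'])}")
        total = acc["n_cr"] + acc["n_pr"]
        lines.append(f"  balanced: {fmt(acc['balanced'], total)}")
        if acc["n_excluded"]:
            lines.append(f"  excluded (no significant readout): {acc['n_excluded']}")
    return "\n".join(lines)
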