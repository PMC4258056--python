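"""End-to-end pipeline: hits -> evidence -> calibration -> consensus -> metrics.

This is the library face of the command-line ``run`` subcommand.  A run
is described by a flat configuration mapping (usually loaded from YAML):

.. code-block:: yaml

    seed: 1                 # master seed; every stage seed derives from it
    measure: sms            # count | sum | mean | sms
    model: gamma            # gamma (SEM) | gaussian (EM)
    consensus: 3            # consensus level c
    simulate:               # either simulate replicates ...
      n_functions: 1000
      fraction_present: 0.3
      n_replicates: 5
    # samples:              # ... or read real per-sample hit tables
    #   - path: rep1.m8
    #     dialect: m8
    # mapping: subject2ko.tsv
    # positives: pos.txt
    # universe: universe.txt

Every replicate is processed independently (parse, best-hit resolution,
evidence, its own mixture fit and threshold); the per-sample calls are
then combined by consensus and, when a reference annotation is available,
scored.  All artefacts are written under ``outdir`` and all randomness is
derived deterministically from the master seed, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import assignments_io, evidence as evidence_mod, mixture, prediction as prediction_mod
from .evaluation import (
    AnnotationReference,
    confusion,
    max_f1,
    roc_auc,
    write_metrics_json,
)
from .synthetic import ExperimentSpec, simulate_hit_tables

__all__ = ["PipelineError", "run_pipeline", "save_fit", "load_fit", "stage_seed"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def stage_seed(master_seed: int, *words: int) -> int:
    """Deterministic per-stage seed derived from the master seed.

    Stays below 2**31 so it can be passed around as a plain C int.
    """
    state = np.random.SeedSequence([int(master_seed), *map(int, words)])
    return int(state.generate_state(1)[0] % (2**31))


def save_fit(
    fit: mixture.MixtureFit,
    threshold: mixture.ThresholdResult,
    path: str | os.PathLike,
    provenance: Mapping[str, Any] | None = None,
) -> None:
    """Persist a fit plus its threshold (and provenance) as JSON."""
    payload = {
        "model": "gaussian" if isinstance(fit, mixture.GaussianMixtureFit) else "gamma",
        "fit": {
            k: v
            for k, v in dataclasses.asdict(fit).items()
            if k != "log_likelihood_trace"
        },
        "threshold": dataclasses.asdict(threshold),
        "provenance": dict(provenance or {}),
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_fit(path: str | os.PathLike) -> tuple[mixture.MixtureFit, mixture.ThresholdResult, dict]:
    with open(path, "rt", encoding="utf-8") as fh:
        payload = json.load(fh)
    cls = (
        mixture.GaussianMixtureFit
        if payload["model"] == "gaussian"
        else mixture.GammaMixtureFit
    )
    fit = cls(**payload["fit"])
    threshold = mixture.ThresholdResult(**payload["threshold"])
    return fit, threshold, payload.get("provenance", {})


def _file_digest(path: str | os.PathLike) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def calibrate_evidence(
    evidence_table: evidence_mod.EvidenceTable,
    measure: str,
    model: str,
    seed: int = 1,
    cost_ratio: float = 1.0,
) -> tuple[mixture.MixtureFit, mixture.ThresholdResult]:
    """Fit the requested mixture to one sample's evidence and derive the
    decision threshold.

    For the Gamma model, values with non-positive measure (possible under
    exotic scoring schemes) violate the support and are excluded from the
    fit with a logged count; the Gaussian model uses all values.
    """
    values = evidence_table.values_for(measure).to_numpy(dtype=float)
    if model == "gaussian":
        fit = mixture.fit_gaussian_em(values)
    elif model == "gamma":
        positive = values > 0
        n_dropped = int((~positive).sum())
        if n_dropped:
            log.info(
                "%s: excluded %d non-positive %s values from the Gamma fit",
                evidence_table.sample_id,
                n_dropped,
                measure,
            )
        fit = mixture.fit_gamma_sem(values[positive], seed=seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    threshold = mixture.derive_threshold(fit, cost_ratio=cost_ratio)
    return fit, threshold


def _load_samples(config: Mapping[str, Any]) -> list[assignments_io.HitTable]:
    mapping = None
    if config.get("mapping"):
        mapping = assignments_io.load_mapping(config["mapping"])
    tables = []
    for i, entry in enumerate(config["samples"]):
        path = entry["path"]
        if not os.path.exists(path):
            raise PipelineError(f"parse: input file not found: {path}")
        table = assignments_io.parse_hit_table(
            path,
            dialect=entry.get("dialect", "generic3"),
            mapping=mapping,
            sample_id=entry.get("sample_id", Path(path).stem),
            max_e_value=entry.get("max_e_value"),
        )
        tables.append(assignments_io.resolve_best_hits(table))
    return tables


def run_pipeline(config: Mapping[str, Any], outdir: str | os.PathLike) -> dict[str, Any]:
    """Execute the configured stages; returns a summary dictionary.

    Raises :class:`PipelineError` naming the failing stage.  Artefacts
    (hit tables when simulating, per-sample evidence, fits, predictions,
    the consensus set and ``metrics.json``) are written under *outdir*.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 1))
    measure = str(config.get("measure", "sms"))
    model = str(config.get("model", "gamma"))
    consensus_c = int(config.get("consensus", 1))
    cost_ratio = float(config.get("cost_ratio", 1.0))

    reference: AnnotationReference | None = None

    # --- stage: inputs (simulate or parse) ---------------------------------
    try:
        if "simulate" in config:
            spec = ExperimentSpec(**{**config["simulate"], "seed": seed})
            tables, present, universe = simulate_hit_tables(spec)
            reference = AnnotationReference(
                positives=frozenset(present), universe=frozenset(universe)
            )
            (out / "truth_positives.txt").write_text(
                "\n".join(sorted(present)) + "\n", encoding="utf-8"
            )
            (out / "universe.txt").write_text(
                "\n".join(sorted(universe)) + "\n", encoding="utf-8"
            )
            for table in tables:
                assignments_io.write_hit_table(table, out / f"hits_{table.sample_id}.tsv")
        elif "samples" in config:
            tables = _load_samples(config)
        else:
            raise PipelineError("inputs: config needs a 'simulate' or 'samples' section")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise PipelineError(f"inputs: {exc}") from exc

    if reference is None and config.get("positives") and config.get("universe"):
        for key in ("positives", "universe"):
            if not os.path.exists(config[key]):
                raise PipelineError(f"evaluate: input file not found: {config[key]}")
        reference = AnnotationReference.from_files(config["positives"], config["universe"])

    log.info("inputs: %d replicate hit tables", len(tables))

    # --- stages: evidence, calibrate, predict (per replicate) --------------
    predictions = []
    per_sample: dict[str, Any] = {}
    for rep_index, table in enumerate(tables):
        try:
            ev = evidence_mod.compute_evidence(table)
            evidence_path = out / f"evidence_{table.sample_id}.tsv"
            evidence_mod.write_evidence(ev, evidence_path)
            log.info("evidence: %s -> %d functions", table.sample_id, len(ev))

            fit, threshold = calibrate_evidence(
                ev,
                measure,
                model,
                seed=stage_seed(seed, 1, rep_index),
                cost_ratio=cost_ratio,
            )
            fit_path = out / f"fit_{table.sample_id}.json"
            save_fit(
                fit,
                threshold,
                fit_path,
                provenance={
                    "sample_id": table.sample_id,
                    "measure": measure,
                    "model": model,
                    "evidence_sha256": _file_digest(evidence_path),
                    "master_seed": seed,
                },
            )

            pred = prediction_mod.filter_by_threshold(
                ev,
                measure,
                threshold.threshold,
                provenance={"model": model, "fallback_used": threshold.fallback_used},
            )
            prediction_mod.write_predictions(pred, out / f"pred_{table.sample_id}.tsv")
            log.info(
                "predict: %s -> %d functions above threshold %.4g",
                table.sample_id,
                len(pred),
                threshold.threshold,
            )
            predictions.append(pred)
            per_sample[table.sample_id] = {
                "n_hits": len(table),
                "n_functions_with_evidence": len(ev),
                "threshold": threshold.threshold,
                "fallback_used": threshold.fallback_used,
                "n_predicted": len(pred),
            }
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"calibrate[{table.sample_id}]: {exc}") from exc

    # --- stage: consensus ---------------------------------------------------
    try:
        cons = prediction_mod.consensus(predictions, consensus_c)
        prediction_mod.write_predictions(cons, out / "consensus.tsv")
        log.info("consensus: c=%d -> %d functions", consensus_c, len(cons))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"consensus: {exc}") from exc

    summary: dict[str, Any] = {
        "seed": seed,
        "measure": measure,
        "model": model,
        "consensus_c": consensus_c,
        "samples": per_sample,
        "n_consensus": len(cons),
    }

    # --- stage: evaluate ----------------------------------------------------
    if reference is not None:
        try:
            rows = {}
            aucs = {}
            max_f1s = {}
            for table, pred in zip(tables, predictions):
                rows[pred.label] = confusion(pred, reference)
                ev = evidence_mod.read_evidence(out / f"evidence_{table.sample_id}.tsv")
                scores = ev.values_for(measure).to_dict()
                aucs[pred.label] = roc_auc(scores, reference).auc
                max_f1s[pred.label] = max_f1(scores, reference)
            rows[cons.label] = confusion(cons, reference)
            write_metrics_json(
                rows,
                out / "metrics.json",
                auc=aucs,
                max_f1=max_f1s,
                seed=seed,
                measure=measure,
                model=model,
                consensus_c=consensus_c,
            )
            summary["metrics"] = {label: m.as_dict() for label, m in rows.items()}
            summary["auc"] = aucs
            summary["max_f1"] = max_f1s
            log.info(
                "evaluate: consensus TPR %.2f%% FPR %.2f%% F1 %.2f%%",
                rows[cons.label].tpr,
                rows[cons.label].fpr,
                rows[cons.label].f1,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"evaluate: {exc}") from exc

    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
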