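"""Presence calls from thresholded evidence, and replicate consensus.

A function is called present in one sample when its evidence value lies
strictly above the calibrated threshold.  Across technical replicates a
consensus vote tightens the call: a function is present overall when it
is predicted in at least ``c`` replicates.  Raising ``c`` can only shrink
the consensus set, which is what drives the falling false-positive rate
at higher consensus levels.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .evidence import EvidenceTable, MEASURES

__all__ = ["PredictionSet", "filter_by_threshold", "consensus", "read_predictions", "write_predictions"]


@dataclass(frozen=True)
class PredictionSet:
    """Function ids called present, for one sample or a consensus.

    ``provenance`` carries the measure, model, threshold(s) and consensus
    level that produced the set (consensus level 0 for a single sample).
    """

    label: str
    functions: frozenset[str]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.functions)


def filter_by_threshold(
    evidence: EvidenceTable,
    measure: str,
    threshold: float,
    provenance: Mapping[str, object] | None = None,
) -> PredictionSet:
    """Call present every function whose *measure* value is strictly
    greater than *threshold* (a value equal to the threshold is excluded).
    """
    values = evidence.values_for(measure)
    present = frozenset(values.index[values > threshold])
    prov = {
        "measure": measure,
        "threshold": float(threshold),
        "consensus_c": 0,
    }
    if provenance:
        prov.update(provenance)
    return PredictionSet(label=evidence.sample_id, functions=present, provenance=prov)


def consensus(predictions: Sequence[PredictionSet], c: int) -> PredictionSet:
    """Functions predicted present in at least *c* of the replicates.

    ``c = 1`` is the union of the inputs and ``c = len(predictions)`` the
    intersection; the result is monotone non-increasing in *c*.
    """
    if not predictions:
        raise ValueError("consensus requires at least one prediction set")
    if not 1 <= c <= len(predictions):
        raise ValueError(
            f"consensus level c={c} out of range [1, {len(predictions)}]"
        )
    votes = Counter()
    for prediction in predictions:
        votes.update(prediction.functions)
    present = frozenset(f for f, v in votes.items() if v >= c)
    prov = {
        "consensus_c": int(c),
        "replicates": tuple(p.label for p in predictions),
        "thresholds": tuple(
            p.provenance.get("threshold") for p in predictions
        ),
    }
    measures = {p.provenance.get("measure") for p in predictions}
    if len(measures) == 1:
        prov["measure"] = measures.pop()
    return PredictionSet(label=f"consensus@{c}", functions=present, provenance=prov)


def write_predictions(prediction: PredictionSet, path: str | os.PathLike) -> None:
    """Write a prediction TSV (label, function_id; sorted for stability)."""
    frame = pd.DataFrame(
        {"label": prediction.label, "function_id": sorted(prediction.functions)}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | os.PathLike) -> PredictionSet:
    """Read a prediction TSV written by :func:`write_predictions`."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    labels = frame["label"].unique()
    if len(labels) > 1:
        raise ValueError(f"prediction table mixes labels: {sorted(labels)}")
    label = labels[0] if len(labels) else "prediction"
    return PredictionSet(label=label, functions=frozenset(frame["function_id"]))
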