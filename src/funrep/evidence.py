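"""Per-function evidence measures from a best-hit-resolved hit table.

For every function f with at least one assigned read the four evidence
measures are, writing H_f for the multiset of hit scores and n_f = |H_f|:

* ``count``             — n_f
* ``sum_of_scores``     — sum of H_f
* ``mean_score``        — mean of H_f
* ``scaled_mean_score`` — mean_score x ln(1 + n_f) / ln(1 + max_g n_g)

count and sum-of-scores track transcript abundance and are therefore
biased by expression level; the mean-based measures are largely free of
that bias.  The scaled mean-score (SMS) damps means that rest on very few
hits by the ratio of log-scaled counts, so the function with the sample's
maximum count keeps its plain mean while sparsely hit functions are pulled
down.  The natural log with the +1 shift keeps the ratio finite and in
(0, 1] for n_f >= 1 (the log base cancels in the ratio) and keeps SMS
positive whenever the mean is positive, as required for Gamma-mixture
modelling downstream.

Functions with zero hits carry no evidence entry: they never enter a
mixture fit and are predicted absent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .assignments_io import HitTable

__all__ = ["EvidenceTable", "MEASURES", "compute_evidence", "read_evidence", "write_evidence"]

#: Short measure names (as used on the CLI) to evidence-frame columns.
MEASURES: Mapping[str, str] = {
    "count": "count",
    "sum": "sum_of_scores",
    "mean": "mean_score",
    "sms": "scaled_mean_score",
}

EVIDENCE_COLUMNS = ("function_id", "count", "sum_of_scores", "mean_score", "scaled_mean_score")


@dataclass(frozen=True)
class EvidenceTable:
    """Per-function evidence values of one sample.

    ``frame`` has one row per function with >= 1 hit and columns
    ``function_id, count, sum_of_scores, mean_score, scaled_mean_score``.
    """

    sample_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVIDENCE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"evidence frame lacks columns {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def max_count(self) -> int:
        """Largest per-function hit count in this sample (0 when empty)."""
        return int(self.frame["count"].max()) if len(self.frame) else 0

    def values_for(self, measure: str) -> pd.Series:
        """Evidence values for a measure, indexed by function_id.

        *measure* may be a short name (``sms``) or a column name.
        """
        column = MEASURES.get(measure, measure)
        if column not in self.frame.columns:
            raise KeyError(f"unknown evidence measure {measure!r}")
        return self.frame.set_index("function_id")[column]


def compute_evidence(table: HitTable) -> EvidenceTable:
    """Aggregate a best-hit-resolved hit table into all four measures.

    Raises ``ValueError`` when the table is not best-hit resolved: with
    ambiguous multi-hit reads still present the counts would double-count
    reads.  An empty table yields an empty evidence table.
    """
    if not table.best_hit_resolved:
        raise ValueError(
            "hit table must be best-hit resolved before evidence aggregation"
        )
    if len(table) == 0:
        frame = pd.DataFrame({c: [] for c in EVIDENCE_COLUMNS})
        frame["count"] = frame["count"].astype(int)
        return EvidenceTable(sample_id=table.sample_id, frame=frame)

    grouped = (
        table.frame.groupby("function_id", sort=True)["score"]
        .agg(count="size", sum_of_scores="sum", mean_score="mean")
        .reset_index()
    )
    max_count = int(grouped["count"].max())
    grouped["scaled_mean_score"] = (
        grouped["mean_score"] * np.log1p(grouped["count"]) / np.log1p(max_count)
    )
    return EvidenceTable(sample_id=table.sample_id, frame=grouped)


def write_evidence(evidence: EvidenceTable, path: str | os.PathLike) -> None:
    """Write the evidence TSV (sample_id + the four measure columns)."""
    out = evidence.frame.copy()
    out.insert(0, "sample_id", evidence.sample_id)
    out.to_csv(path, sep="\t", index=False)


def read_evidence(path: str | os.PathLike) -> EvidenceTable:
    """Read an evidence TSV written by :func:`write_evidence`."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "function_id": str})
    sample_ids = frame["sample_id"].unique()
    if len(sample_ids) > 1:
        raise ValueError(f"evidence table mixes sample_ids: {sorted(sample_ids)}")
    sample_id = sample_ids[0] if len(sample_ids) else "sample"
    frame = frame.drop(columns=["sample_id"]).reset_index(drop=True)
    return EvidenceTable(sample_id=sample_id, frame=frame)
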