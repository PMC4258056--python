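"""Parsing of homology-search hit tables and best-hit resolution.

Homology search tools (BLASTX, RAPSearch and friends) report, for every
sequencing read, one or more hits against functionally annotated protein
sequences together with an alignment quality score.  This module turns the
two supported on-disk dialects into a uniform in-memory :class:`HitTable`
and resolves each read's ambiguous hits down to its single best hit.

Supported dialects:

``m8``
    The 12-column BLAST tabular format (``-outfmt 6``): query, subject,
    identity, alignment length, mismatches, gap opens, qstart, qend,
    sstart, send, E-value, bit score.  Subject accessions are translated
    to function identifiers (e.g. KEGG ortholog accessions) through a
    mandatory two-column mapping; hits whose subject has no mapping entry
    are dropped and counted.

``generic3``
    A pre-mapped three-column table: read_id, function_id, score.  This is
    the adapter for tools whose native output is not BLAST tabular.

Scores are treated as opaque reals; scores from different dialects or
tools are never mixed within one analysis.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HitRecord",
    "HitTable",
    "HitTableParseError",
    "load_mapping",
    "parse_hit_table",
    "resolve_best_hits",
    "read_hit_table",
    "write_hit_table",
]

log = logging.getLogger(__name__)

#: Column order of the canonical in-memory hit frame.
HIT_COLUMNS = ("read_id", "function_id", "score", "e_value")

DIALECTS = ("m8", "generic3")

TIE_POLICIES = ("lexicographic_function_id",)


class HitTableParseError(ValueError):
    """Raised when an input line cannot be parsed; names the line number."""


@dataclass(frozen=True)
class HitRecord:
    """A single read-to-function assignment.

    ``score`` is a dimensionless alignment quality (e.g. a bit score);
    ``e_value`` is the optional expectation value of the hit.
    """

    read_id: str
    function_id: str
    score: float
    e_value: float | None = None

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if not self.function_id:
            raise ValueError("function_id must be non-empty")
        if self.e_value is not None and self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")


@dataclass(frozen=True)
class HitTable:
    """All hits of one sample, as a pandas frame with columns
    ``read_id, function_id, score, e_value`` (``e_value`` is NaN when the
    dialect carries none).

    When ``best_hit_resolved`` is true every read occurs exactly once.
    ``n_unmapped_dropped`` counts m8 lines whose subject accession had no
    function mapping.
    """

    sample_id: str
    frame: pd.DataFrame
    best_hit_resolved: bool = False
    n_unmapped_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in HIT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"hit frame lacks columns {missing}")
        if self.best_hit_resolved and self.frame["read_id"].duplicated().any():
            raise ValueError("best_hit_resolved table has duplicate read_ids")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_reads(self) -> int:
        return self.frame["read_id"].nunique()

    def records(self) -> Iterable[HitRecord]:
        """Iterate over rows as :class:`HitRecord` objects."""
        for row in self.frame.itertuples(index=False):
            ev = None if pd.isna(row.e_value) else float(row.e_value)
            yield HitRecord(row.read_id, row.function_id, float(row.score), ev)


def load_mapping(source: str | os.PathLike | IO[str]) -> dict[str, str]:
    """Read a two-column TSV mapping subject accessions to function ids.

    Lines starting with ``#`` are ignored.
    """
    mapping: dict[str, str] = {}
    with _as_text_stream(source) as (stream, _name):
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise HitTableParseError(
                    f"mapping line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            mapping[fields[0]] = fields[1]
    return mapping


def _as_text_stream(source):
    """Context manager yielding (stream, display_name) for a path or stream."""
    import contextlib

    @contextlib.contextmanager
    def _cm():
        if hasattr(source, "read"):
            yield source, getattr(source, "name", "<stream>")
        else:
            with open(source, "rt", encoding="utf-8") as fh:
                yield fh, str(source)

    return _cm()


def _parse_float(text: str, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise HitTableParseError(
            f"line {lineno}: cannot parse {what} from {text!r}"
        ) from None


def parse_hit_table(
    source: str | os.PathLike | IO[str],
    dialect: str,
    mapping: Mapping[str, str] | None = None,
    sample_id: str = "sample",
    max_e_value: float | None = None,
) -> HitTable:
    """Parse one sample's homology-search output into a :class:`HitTable`.

    Parameters
    ----------
    source
        Path or readable text stream.
    dialect
        ``"m8"`` (12-column BLAST tabular; requires *mapping*) or
        ``"generic3"`` (read_id, function_id, score).
    mapping
        Subject accession to function id translation, mandatory for m8.
        Subjects without an entry are dropped and counted.
    max_e_value
        Optional filter: hits with an E-value above this are dropped.
        Liberal search cutoffs are normally the upstream tool's business,
        so no filter is applied by default.

    Lines beginning with ``#`` and blank lines are skipped in every
    dialect.  Malformed lines raise :class:`HitTableParseError` naming the
    line number.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "m8" and mapping is None:
        raise ValueError("dialect 'm8' requires a subject-to-function mapping")

    read_ids: list[str] = []
    function_ids: list[str] = []
    scores: list[float] = []
    e_values: list[float] = []
    n_unmapped = 0

    with _as_text_stream(source) as (stream, name):
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "m8":
                if len(fields) != 12:
                    raise HitTableParseError(
                        f"line {lineno}: m8 requires 12 tab-separated columns, "
                        f"got {len(fields)}"
                    )
                subject = fields[1]
                function_id = mapping.get(subject)
                if function_id is None:
                    n_unmapped += 1
                    continue
                e_value = _parse_float(fields[10], lineno, "E-value")
                score = _parse_float(fields[11], lineno, "bit score")
                read_ids.append(fields[0])
                function_ids.append(function_id)
                scores.append(score)
                e_values.append(e_value)
            else:  # generic3
                if len(fields) != 3:
                    raise HitTableParseError(
                        f"line {lineno}: generic3 requires 3 tab-separated "
                        f"columns, got {len(fields)}"
                    )
                score = _parse_float(fields[2], lineno, "score")
                read_ids.append(fields[0])
                function_ids.append(fields[1])
                scores.append(score)
                e_values.append(np.nan)

    frame = pd.DataFrame(
        {
            "read_id": pd.Series(read_ids, dtype=object),
            "function_id": pd.Series(function_ids, dtype=object),
            "score": np.asarray(scores, dtype=float),
            "e_value": np.asarray(e_values, dtype=float),
        }
    )
    if max_e_value is not None:
        keep = ~(frame["e_value"] > max_e_value)  # NaN e_values are kept
        frame = frame.loc[keep].reset_index(drop=True)
    if n_unmapped:
        log.info("%s: dropped %d hits with unmapped subjects", sample_id, n_unmapped)
    if frame.empty:
        log.warning("%s: no hits parsed from %s", sample_id, name)
    return HitTable(
        sample_id=sample_id,
        frame=frame,
        best_hit_resolved=False,
        n_unmapped_dropped=n_unmapped,
    )


def resolve_best_hits(
    table: HitTable, tie_policy: str = "lexicographic_function_id"
) -> HitTable:
    """Keep, for every read, only the hit with the highest score.

    Score ties are broken by the lexicographically smallest function_id,
    which makes the result reproducible across runs and platforms.  The
    operation is idempotent in effect; by contract it takes an unresolved
    table and returns a resolved one.
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    if table.best_hit_resolved:
        raise ValueError("table is already best-hit resolved")
    frame = table.frame
    if frame.empty:
        return replace(table, best_hit_resolved=True)
    best = (
        frame.sort_values(
            ["read_id", "score", "function_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        .groupby("read_id", sort=True)
        .head(1)
        .reset_index(drop=True)
    )
    return replace(table, frame=best, best_hit_resolved=True)


def write_hit_table(table: HitTable, path: str | os.PathLike) -> None:
    """Write the canonical hit-table TSV.

    Columns: sample_id, read_id, function_id, score, e_value (``NA`` when
    absent); a ``#`` metadata line records the best-hit-resolved flag so a
    round trip preserves it.
    """
    out = table.frame.copy()
    out.insert(0, "sample_id", table.sample_id)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# best_hit_resolved={str(table.best_hit_resolved).lower()}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_hit_table(path: str | os.PathLike) -> HitTable:
    """Read a canonical hit-table TSV written by :func:`write_hit_table`."""
    resolved = False
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            resolved = "best_hit_resolved=true" in first
        else:
            fh.seek(0)
        frame = pd.read_csv(
            fh,
            sep="\t",
            na_values=["NA"],
            dtype={"sample_id": str, "read_id": str, "function_id": str},
        )
    sample_ids = frame["sample_id"].unique()
    if len(sample_ids) > 1:
        raise ValueError(f"hit table mixes sample_ids: {sorted(sample_ids)}")
    sample_id = sample_ids[0] if len(sample_ids) else "sample"
    frame = frame.drop(columns=["sample_id"]).reset_index(drop=True)
    return HitTable(sample_id=sample_id, frame=frame, best_hit_resolved=resolved)
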