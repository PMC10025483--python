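"""Conserved-miRNA cataloguing from collapsed small-RNA reads.

Distinct trimmed read sequences are tallied per library into a count
matrix, filtered by a minimum-count rule (>= 10 counts in at least one
library), and assigned conserved miRNA identities by exact containment
matching against a mature miRNA reference: no substitutions anywhere,
length differences within a bound accepted (the read may over- or
underhang the mature sequence). Length/end variants (isomiRs) mapping to
the same miRNA name are collapsed to a single canonical sequence — the
most abundant variant across all libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MiRNAAssignment:
    """One collapsed read matched to one mature reference entry.

    ``length_diff`` is |read| - |mature| (negative for reads shorter than
    the mature sequence); ``is_canonical`` marks the isomiR-collapsing
    survivor for the miRNA name.
    """

    sequence: str
    mirna_name: str
    length_diff: int
    is_canonical: bool = False


def collapse_reads(reads_per_library: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Tally distinct sequences per library into a counts DataFrame.

    Rows are distinct sequences, columns library IDs, values non-negative
    integers. Column sums equal the number of input reads per library.
    Empty libraries yield an all-zero column (with a warning).
    """
    columns = {}
    for library_id, reads in reads_per_library.items():
        tally: dict[str, int] = {}
        for seq in reads:
            tally[seq] = tally.get(seq, 0) + 1
        if not tally:
            logger.warning("library %s contains no reads", library_id)
        columns[library_id] = tally
    matrix = pd.DataFrame(columns).fillna(0).astype(int)
    matrix.index.name = "sequence"
    return matrix.sort_index()


def filter_min_count(matrix: pd.DataFrame, threshold: int = 10) -> pd.DataFrame:
    """Keep rows whose maximum count over libraries is >= threshold.

    The boundary is inclusive: a row with exactly ``threshold`` counts in
    a single library survives.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if matrix.empty:
        return matrix
    return matrix.loc[matrix.max(axis=1) >= threshold]


def match_reference(
    sequence: str,
    reference: Mapping[str, str],
    max_length_diff: int = 4,
) -> list[MiRNAAssignment]:
    """Match one read against a mature miRNA reference by exact containment.

    A match is reported iff the shorter of (read, mature) is an exact
    substring of the longer — zero substitutions anywhere — and the length
    difference is within ``max_length_diff``. Matches are sorted by
    (|length_diff| ascending, reference ID lexicographic).
    """
    if not reference:
        raise ValueError("empty mature miRNA reference")
    hits: list[MiRNAAssignment] = []
    for name, mature in reference.items():
        diff = len(sequence) - len(mature)
        if abs(diff) > max_length_diff:
            continue
        if diff >= 0:
            contained = mature in sequence
        else:
            contained = sequence in mature
        if contained:
            hits.append(MiRNAAssignment(sequence, name, diff))
    hits.sort(key=lambda a: (abs(a.length_diff), a.mirna_name))
    return hits


def assign_reads(
    matrix: pd.DataFrame,
    reference: Mapping[str, str],
    max_length_diff: int = 4,
) -> list[MiRNAAssignment]:
    """Assign every matrix row to its single best reference match.

    Reads matching several miRNA names keep only the best-ranked match
    (smallest |length_diff|, ties broken lexicographically by name);
    cross-family ambiguity is logged. Unmatched reads are dropped.
    """
    assignments = []
    for seq in matrix.index:
        hits = match_reference(seq, reference, max_length_diff)
        if not hits:
            continue
        if len(hits) > 1:
            logger.info(
                "read %s matches %d reference entries; keeping %s",
                seq, len(hits), hits[0].mirna_name,
            )
        assignments.append(hits[0])
    return assignments


def collapse_isomirs(
    assignments: Sequence[MiRNAAssignment],
    matrix: pd.DataFrame,
) -> list[MiRNAAssignment]:
    """Flag one canonical sequence per miRNA name.

    The canonical variant is the one with the highest total count across
    libraries; ties break to the smaller |length_diff|, then to the
    lexicographically smallest sequence. Returns new assignment objects
    with ``is_canonical`` set; non-canonical entries are retained in the
    list (callers exclude them from per-miRNA counts).
    """
    missing = [a.sequence for a in assignments if a.sequence not in matrix.index]
    if missing:
        raise KeyError(f"assignments reference sequences absent from matrix: {missing[:3]}")
    totals = matrix.sum(axis=1)
    by_name: dict[str, list[MiRNAAssignment]] = {}
    for a in assignments:
        by_name.setdefault(a.mirna_name, []).append(a)
    canonical_seq = {
        name: min(
            group,
            key=lambda a: (-int(totals[a.sequence]), abs(a.length_diff), a.sequence),
        ).sequence
        for name, group in by_name.items()
    }
    return [
        MiRNAAssignment(
            a.sequence, a.mirna_name, a.length_diff,
            is_canonical=(a.sequence == canonical_seq[a.mirna_name]),
        )
        for a in assignments
    ]


def mirna_counts(
    assignments: Sequence[MiRNAAssignment], matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-miRNA count matrix from canonical assignments only."""
    rows = {a.mirna_name: matrix.loc[a.sequence] for a in assignments if a.is_canonical}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "mirna_name"
    return out.sort_index()


def mean_expression(row: pd.Series, libraries: Sequence[str]) -> float:
    """Arithmetic mean count over exactly six libraries.

    The study's convention: mean over the two conditions of one contrast
    (3 control + 3 treated replicates).
    """
    if len(libraries) != 6:
        raise ValueError(f"mean_expression requires exactly 6 libraries, got {len(libraries)}")
    return float(row.loc[list(libraries)].mean())
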