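"""Readers and writers for the pipeline's file formats.

Covers 4-line FASTQ, FASTA (via Biopython), tab-separated sample sheets,
and the two fixtures transcribed from the printed study tables: the 58-row
table of differentially accumulated miRNAs and the ABA content measurements.

All sequences are held internally in the DNA alphabet: ``U`` is normalized
to ``T`` on load, so downstream exact-matching operations never have to
consider RNA/DNA spelling differences.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO

CONDITIONS = ("control_1", "drought", "control_2", "rehydration")

P_CLASSES = ("ns", "p05", "p01", "p001")

_STAR_TO_CLASS = {"": "ns", "*": "p05", "**": "p01", "***": "p001"}

_U_TO_T = str.maketrans("Uu", "Tt")


class FastqParseError(ValueError):
    """Raised for a malformed FASTQ record; carries the record index."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"FASTQ record {record_index}: {message}")


@dataclass(frozen=True)
class FastqRecord:
    read_id: str
    sequence: str
    quality: str


DISCARD = None  # sentinel returned by trim_adapter for dropped reads


def read_fastq(path: str | Path | TextIO) -> Iterator[FastqRecord]:
    """Yield records from a 4-line FASTQ file in file order.

    ``U`` bases are normalized to ``T``. A truncated record, a header not
    starting with ``@``, or a sequence/quality length mismatch raises
    :class:`FastqParseError` naming the (0-based) record index.
    """
    if hasattr(path, "read"):
        yield from _parse_fastq(path)
    else:
        with open(path) as fh:
            yield from _parse_fastq(fh)


def _parse_fastq(fh: TextIO) -> Iterator[FastqRecord]:
    index = 0
    while True:
        header = fh.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header:  # trailing blank line(s)
            if fh.readline():
                raise FastqParseError(index, "blank line inside file")
            return
        seq = fh.readline().rstrip("\n")
        plus = fh.readline().rstrip("\n")
        qual = fh.readline().rstrip("\n")
        if not header.startswith("@"):
            raise FastqParseError(index, f"header does not start with '@': {header!r}")
        if not plus.startswith("+"):
            raise FastqParseError(index, "separator line does not start with '+'")
        if len(seq) != len(qual):
            raise FastqParseError(
                index, f"sequence length {len(seq)} != quality length {len(qual)}"
            )
        yield FastqRecord(header[1:].split()[0] if header[1:] else "", seq.translate(_U_TO_T).upper(), qual)
        index += 1


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> int:
    """Write records as 4-line FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    IDs are taken up to the first whitespace; sequences are uppercased
    and U-normalized. Duplicate IDs raise ``ValueError``.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        out[rec.id] = str(rec.seq).upper().translate(_U_TO_T)
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def trim_adapter(sequence: str, adapter: str, min_len: int = 14) -> str | None:
    """Trim a 3' adapter by its first 6 nt; return the insert or DISCARD.

    The read is truncated at the leftmost exact occurrence of the adapter
    prefix (first 6 nt, or the whole adapter if shorter). Reads without the
    adapter are returned unchanged; trimmed reads shorter than ``min_len``
    and empty input return ``DISCARD`` (None).
    """
    if len(adapter) < 6:
        probe = adapter
    else:
        probe = adapter[:6]
    if not probe:
        raise ValueError("adapter must be non-empty")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not sequence:
        return DISCARD
    pos = sequence.find(probe)
    if pos == -1:
        return sequence
    trimmed = sequence[:pos]
    if len(trimmed) < min_len:
        return DISCARD
    return trimmed


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Load a sample sheet TSV (library_id, condition, replicate).

    Validates unique library IDs, known condition labels and positive
    integer replicates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str, "condition": str})
    return validate_sample_sheet(df)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    required = {"library_id", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["library_id"].duplicated().any():
        dupes = df.loc[df["library_id"].duplicated(), "library_id"].tolist()
        raise ValueError(f"duplicate library_ids: {dupes}")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}; expected {CONDITIONS}")
    if (df["replicate"].astype(int) < 1).any():
        raise ValueError("replicate numbers must be positive integers")
    df = df.copy()
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(df).to_csv(path, sep="\t", index=False)


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("mirstress").joinpath("data", name)))


def _parse_decimal(value) -> float:
    """Parse a printed number, tolerating a decimal comma ("-1,93" -> -1.93)."""
    if isinstance(value, str):
        value = value.strip().replace(",", ".")
    return float(value)


def load_table2_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged 58-row table of differentially accumulated miRNAs.

    Columns: mirna_name, log2fc_drought, p_class_drought, log2fc_rehydration,
    p_class_rehydration. Significance stars are mapped to ``p05``/``p01``/
    ``p001`` and a blank cell to ``ns``; decimal commas in the printed source
    are normalized to points. A row count other than 58 or an unmappable
    significance mark raises ``ValueError`` (fixture-integrity error).
    """
    if path is None:
        path = _data_path("table2_de_mirnas.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(df) != 58:
        raise ValueError(f"fixture integrity: expected 58 rows, found {len(df)}")
    out = pd.DataFrame()
    out["mirna_name"] = df["mirna_name"]
    for contrast in ("drought", "rehydration"):
        out[f"log2fc_{contrast}"] = df[f"log2fc_{contrast}"].map(_parse_decimal)
        stars = df[f"p_class_{contrast}"].str.strip()
        unknown = set(stars) - set(_STAR_TO_CLASS)
        if unknown:
            raise ValueError(f"fixture integrity: unmappable significance marks {unknown}")
        out[f"p_class_{contrast}"] = stars.map(_STAR_TO_CLASS)
    if out["mirna_name"].duplicated().any():
        raise ValueError("fixture integrity: duplicate miRNA names")
    return out


def load_aba_content(path: str | Path | None = None) -> pd.Series:
    """Load the packaged ABA content measurements (ng per g fresh weight).

    Returns a Series indexed by condition: control_1 304, drought 14991,
    control_2 158, rehydration 1913.
    """
    if path is None:
        path = _data_path("aba_content.tsv")
    df = pd.read_csv(path, sep="\t")
    return df.set_index("condition")["aba_ng_per_g_fw"].astype(float)
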