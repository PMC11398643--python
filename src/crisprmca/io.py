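"""Readers and writers for the toolkit's text formats.

One dataset dialect is used throughout: delimited text with a mandatory
``guide,target[,label]`` header, one record per line, ``_`` denoting a
bulge gap (TSV accepted via ``delimiter="\\t"``).  Genomes are FASTA
(parsed with Biopython).  Candidate off-target sites use the six-column
tab-separated layout popularized by Cas-Offinder (pattern, chromosome,
position, matched sequence, strand, mismatch count), so output from the
genuine tool can be consumed interchangeably with this package's scanner.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import CrisprMcaError, DatasetFormatError
from .esb import OffTargetCandidate
from .pairs import GuideTargetPair

# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def read_dataset(path: str | Path, delimiter: str = ",") -> list[GuideTargetPair]:
    """Read, normalize and validate a guide/target dataset file.

    Malformed records are collected and reported together with their
    1-based line numbers.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        raise DatasetFormatError(f"{path}: empty dataset file") from None
    cols = [c.strip().lower() for c in frame.columns]
    frame.columns = cols
    if "guide" not in cols or "target" not in cols:
        raise DatasetFormatError(f"{path}: header must contain 'guide' and 'target'")
    if len(frame) == 0:
        raise DatasetFormatError(f"{path}: no records")
    has_label = "label" in cols
    pairs: list[GuideTargetPair] = []
    problems: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        label = None
        if has_label:
            raw = getattr(row, "label")
            if not (isinstance(raw, float) and pd.isna(raw)):
                try:
                    label = int(raw)
                except (TypeError, ValueError):
                    problems.append(f"line {line_no}: non-integer label {raw!r}")
                    continue
        try:
            pairs.append(
                GuideTargetPair.from_raw(
                    getattr(row, "guide"), getattr(row, "target"),
                    label=label, source_id=f"{path.name}:{line_no}",
                )
            )
        except CrisprMcaError as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise DatasetFormatError(
            f"{path}: {len(problems)} malformed record(s):\n  " + "\n  ".join(problems)
        )
    return pairs


def write_dataset(pairs: list[GuideTargetPair], path: str | Path, delimiter: str = ",") -> None:
    frame = pd.DataFrame(
        {
            "guide": [p.guide for p in pairs],
            "target": [p.target for p in pairs],
            "label": [p.label for p in pairs],
        }
    )
    frame.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> uppercase sequence; wrapped lines concatenated; duplicate ids rejected."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise DatasetFormatError(f"{path}: duplicate FASTA id {record.id!r}")
        out[record.id] = str(record.seq).upper()
    if not out:
        raise DatasetFormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# candidate sites (Cas-Offinder-compatible layout)
# ---------------------------------------------------------------------------

_CASOFF_COLUMNS = 6


def write_casoffinder_output(
    candidates: list[OffTargetCandidate], guide: str, path: str | Path
) -> None:
    """Write candidates in the six-column tab-separated interchange layout."""
    pattern = guide + "NGG"
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{pattern}\t{c.chrom}\t{c.start}\t{c.site_seq}\t{c.strand}\t{c.n_mismatch}\n"
            )


def read_casoffinder_output(path: str | Path) -> list[OffTargetCandidate]:
    """Parse a Cas-Offinder-style file into candidates.

    An empty file yields an empty list; a line with the wrong column count
    or a non-integer position/mismatch column raises with its line number.
    """
    out: list[OffTargetCandidate] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != _CASOFF_COLUMNS:
                raise DatasetFormatError(
                    f"{path}: line {i}: expected {_CASOFF_COLUMNS} tab-separated columns, "
                    f"got {len(fields)}"
                )
            _, chrom, pos, matched, strand, n_mm = fields
            try:
                start = int(pos)
                mm = int(n_mm)
            except ValueError:
                raise DatasetFormatError(
                    f"{path}: line {i}: position and mismatch count must be integers"
                ) from None
            if strand not in "+-":
                raise DatasetFormatError(f"{path}: line {i}: strand must be + or -")
            out.append(
                OffTargetCandidate(
                    site_seq=matched.upper(), chrom=chrom, start=start,
                    strand=strand, n_mismatch=mm,
                )
            )
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def save_run_config(config: dict, path: str | Path) -> None:
    """Serialize a fully-resolved run configuration (lossless round-trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise DatasetFormatError(f"{path}: run config must be a mapping")
    return loaded
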