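"""FASTA ingestion.

Thin wrapper over Biopython's FASTA parser: record IDs are truncated at the
first whitespace, sequences are uppercased and line wrapping is transparent.
Duplicate IDs are disambiguated with a numeric suffix (and logged), so the
classifier's one-row-per-query outputs stay keyed uniquely.
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, uppercased sequence).

    An empty file yields an empty list with a warning; text before the first
    header is a malformed-record error naming the line.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            break
        else:
            logger.warning("%s: empty FASTA file", path)
            return []
        fh.seek(0)
        records: list[tuple[str, str]] = []
        seen: dict[str, int] = {}
        for title, seq in SimpleFastaParser(fh):
            rec_id = title.split()[0] if title.split() else "unnamed"
            if rec_id in seen:
                seen[rec_id] += 1
                new_id = f"{rec_id}.{seen[rec_id]}"
                logger.warning("duplicate FASTA id %r renamed to %r", rec_id, new_id)
                rec_id = new_id
            else:
                seen[rec_id] = 0
            records.append((rec_id, seq.upper()))
    return records


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
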