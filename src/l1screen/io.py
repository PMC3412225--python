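"""File-format helpers: FASTA (via Biopython), BED (0-based half-open),
TSV and JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_bed_intervals",
    "write_json",
    "read_json",
]


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """(id, sequence, description) for each record."""
    return [
        (rec.id, str(rec.seq).upper(), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(
    path: str | Path,
    records: list[tuple[str, str]] | dict[str, str],
    descriptions: dict[str, str] | None = None,
) -> None:
    items = records.items() if isinstance(records, dict) else records
    descriptions = descriptions or {}
    seq_records = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in items
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_bed(
    path: str | Path,
    rows: list[tuple],
    header: str | None = None,
) -> None:
    """Rows are (chrom, start, end[, name[, score[, strand]]]), 0-based
    half-open."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """(chrom, start, end) triples from a BED file (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
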