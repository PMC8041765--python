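"""Sequence and metadata I/O.

Reads multi-record protein FASTA plus an optional tab-separated metadata
table binding each accession to a species (and, optionally, lineage tags
such as family and order), and writes the per-record group-call table the
classifier produces.

Conventions
-----------
* FASTA record id = token before the first whitespace in the header; the
  remainder of the header is used as a species fallback when no metadata
  table is supplied (matching typical GenBank / Phytozome exports).
* Duplicate removal keys on ``(species, exact sequence)`` — identical
  sequences observed in *different* species are both retained, as are
  same-species isoforms that differ anywhere in the string.
* Internally all coordinates are 0-based half-open; 1-based positions
  appear only in written tables, matching the field's convention of
  numbering PSPG columns 1..44.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "AMINO_ALPHABET",
    "ProteinRecord",
    "MetadataError",
    "FastaParseError",
    "load_records",
    "dedupe_records",
    "write_fasta",
    "write_metadata_tsv",
    "write_calls_tsv",
    "read_calls_tsv",
]

#: The 20 standard amino acids plus X for ambiguous/low-quality positions.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed or violates the alphabet."""


class MetadataError(ValueError):
    """Raised when the metadata table does not cover the FASTA accessions."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence bound to its source species.

    Parameters
    ----------
    accession : str
        Unique identifier within a dataset.
    species : str
        Binomial species name (free text; used as the census key).
    sequence : str
        Uppercase amino-acid string over the 20-letter alphabet plus X.
    lineage_tags : tuple of str
        Optional ordered lineage labels (e.g. family, order).
    """

    accession: str
    species: str
    sequence: str
    lineage_tags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residue(s) {sorted(bad)!r}; "
                "allowed alphabet is the 20 amino acids plus X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _parse_metadata(metadata_path: Path) -> dict[str, dict[str, str]]:
    rows: dict[str, dict[str, str]] = {}
    with open(metadata_path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "accession" not in reader.fieldnames:
            raise MetadataError(
                f"{metadata_path}: metadata TSV needs an 'accession' column "
                f"(got {reader.fieldnames})"
            )
        for row in reader:
            rows[row["accession"]] = row
    return rows


def dedupe_records(records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Drop records whose ``(species, sequence)`` pair was already seen.

    Keeps the first occurrence; idempotent. Identical sequences from two
    different species survive — cross-species identity is biological
    signal, not redundancy.
    """
    seen: set[tuple[str, str]] = set()
    out: list[ProteinRecord] = []
    for rec in records:
        key = (rec.species, rec.sequence)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def load_records(
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
) -> list[ProteinRecord]:
    """Read a protein FASTA (and optional metadata TSV) into records.

    Species is taken from the metadata table when one is given, otherwise
    from the FASTA header text after the first whitespace. Exact duplicate
    sequences within a species are removed, keeping the first.

    Raises
    ------
    FastaParseError
        If the FASTA is malformed or a sequence leaves the amino alphabet.
    MetadataError
        If a metadata table is given but misses some FASTA accessions.
    """
    fasta_path = Path(fasta_path)
    meta = _parse_metadata(Path(metadata_path)) if metadata_path else None

    records: list[ProteinRecord] = []
    missing: list[str] = []
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        accession = seq_rec.id
        sequence = str(seq_rec.seq).upper()
        if meta is not None:
            row = meta.get(accession)
            if row is None:
                missing.append(accession)
                continue
            species = row.get("species", "") or ""
            tags = tuple(
                row[k] for k in ("family", "order") if row.get(k)
            )
        else:
            # header remainder as species fallback
            parts = seq_rec.description.split(None, 1)
            species = parts[1].strip() if len(parts) > 1 else ""
            tags = ()
        try:
            records.append(
                ProteinRecord(accession=accession, species=species,
                              sequence=sequence, lineage_tags=tags)
            )
        except ValueError as exc:
            raise FastaParseError(f"{fasta_path}: record '{accession}': {exc}") from exc
    if missing:
        raise MetadataError(
            f"{metadata_path}: no metadata row for accession(s): "
            + ", ".join(missing)
        )
    if not records:
        raise FastaParseError(f"{fasta_path}: no records")
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.accession] = counts.get(rec.accession, 0) + 1
    dupes = sorted(a for a, c in counts.items() if c > 1)
    deduped = dedupe_records(records)
    if dupes:
        remaining = [r.accession for r in deduped]
        if len(set(remaining)) != len(remaining):
            raise FastaParseError(
                f"{fasta_path}: duplicate accession(s) with distinct "
                f"(species, sequence): {dupes}"
            )
    return deduped


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as uncompressed FASTA, 60 columns per line."""
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.accession} {rec.species}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                handle.write(rec.sequence[i : i + 60] + "\n")


def write_metadata_tsv(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write the accession/species/family/order table for `load_records`."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "species", "family", "order"])
        for rec in records:
            tags = list(rec.lineage_tags) + ["", ""]
            writer.writerow([rec.accession, rec.species, tags[0], tags[1]])


CALL_COLUMNS = [
    "accession",
    "species",
    "motif_found",
    "motif_start",
    "res41",
    "res42",
    "group",
    "hs_present",
    "submotif_hits_o",
    "submotif_hits_d",
]


def write_calls_tsv(calls: Sequence, path: str | Path) -> None:
    """Write group calls as TSV; motif_start is reported 1-based (0 = none)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CALL_COLUMNS)
        for call in calls:
            writer.writerow(
                [
                    call.accession,
                    call.species,
                    int(call.motif_found),
                    (call.motif_start + 1) if call.motif_found else 0,
                    call.res41,
                    call.res42,
                    call.group,
                    int(call.hs_present),
                    call.submotif_hits_o,
                    call.submotif_hits_d,
                ]
            )


def read_calls_tsv(path: str | Path) -> list[dict[str, object]]:
    """Re-read a call table; numeric columns are converted back."""
    out: list[dict[str, object]] = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            out.append(
                {
                    "accession": row["accession"],
                    "species": row["species"],
                    "motif_found": bool(int(row["motif_found"])),
                    "motif_start": int(row["motif_start"]) - 1
                    if int(row["motif_found"])
                    else None,
                    "res41": row["res41"],
                    "res42": row["res42"],
                    "group": row["group"],
                    "hs_present": bool(int(row["hs_present"])),
                    "submotif_hits_o": int(row["submotif_hits_o"]),
                    "submotif_hits_d": int(row["submotif_hits_d"]),
                }
            )
    return out
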