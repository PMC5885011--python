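"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ parsing is delegated to Biopython; this module adds the
strict validation the downstream entropy math relies on (a 4+1 alphabet,
quality/sequence length agreement, unique identifiers) and attaches sample
identity to every record.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

VALID_RESIDUES = frozenset("ACGTN")

#: sample types of the source study design (snow/ice surface habitats + air)
SAMPLE_TYPES = (
    "clean_snow",
    "dirty_snow",
    "clean_ice",
    "dirty_ice",
    "dispersed_cryoconite",
    "air",
)


class SequenceFormatError(ValueError):
    """Malformed sequence input; parsers fail loudly rather than skip records."""


@dataclass(frozen=True, slots=True)
class SequenceRecord:
    """One amplicon read (or reference sequence) with optional Phred qualities."""

    read_id: str
    residues: str
    qualities: tuple[int, ...] | None = None
    sample_label: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise SequenceFormatError(
                f"record {self.read_id!r}: residues outside A/C/G/T/N: {sorted(bad)}"
            )
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise SequenceFormatError(
                f"record {self.read_id!r}: {len(self.qualities)} quality values for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SampleMap:
    """Sample metadata: label, habitat type and sampling site for each sample."""

    rows: pd.DataFrame  # columns: sample_label, sample_type, site

    REQUIRED = ("sample_label", "sample_type", "site")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"sample map missing columns: {missing}")
        dup = self.rows["sample_label"][self.rows["sample_label"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate sample labels: {sorted(dup.unique())}")

    @property
    def labels(self) -> list[str]:
        return list(self.rows["sample_label"])

    def site_of(self, sample_label: str) -> str:
        hit = self.rows.loc[self.rows["sample_label"] == sample_label, "site"]
        if hit.empty:
            raise KeyError(f"sample {sample_label!r} not in sample map")
        return str(hit.iloc[0])

    def __contains__(self, sample_label: str) -> bool:
        return bool((self.rows["sample_label"] == sample_label).any())

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "SampleMap":
        return cls(pd.DataFrame(records, columns=list(cls.REQUIRED)))


def _default_sample_label(path: str | Path) -> str:
    name = Path(path).name
    for suffix in (".fastq.gz", ".fq.gz", ".fastq", ".fq", ".fasta", ".fa", ".fna"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return os.path.splitext(name)[0]


def read_fastq(path: str | Path, sample_label: str | None = None) -> Iterator[SequenceRecord]:
    """Stream records from a Phred+33 FASTQ file in file order.

    Residues are uppercased; the sample label defaults to the file stem.
    Truncated records and sequence/quality length mismatches raise
    :class:`SequenceFormatError`.
    """
    label = _default_sample_label(path) if sample_label is None else sample_label
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield SequenceRecord(
                read_id=rec.id,
                residues=str(rec.seq).upper(),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
                sample_label=label,
            )
    except ValueError as exc:  # Biopython signals truncation/length mismatch
        raise SequenceFormatError(f"{path}: {exc}") from exc


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> int:
    """Write records as Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as handle:
        for rec in records:
            if rec.qualities is None:
                raise SequenceFormatError(f"record {rec.read_id!r} has no qualities")
            bio = _BioRecord(Seq(rec.residues), id=rec.read_id, description="")
            bio.letter_annotations["phred_quality"] = list(rec.qualities)
            SeqIO.write(bio, handle, "fastq")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, residues)`` pairs.

    Wrapped records are concatenated; duplicate ids are an error. The full
    description line (id + annotation) is preserved in the id slot so taxon
    labels survive.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceFormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        bad = set(residues) - VALID_RESIDUES
        if bad:
            raise SequenceFormatError(
                f"{path}: record {rec.id!r} has residues outside A/C/G/T/N: {sorted(bad)}"
            )
        out.append((rec.description, residues))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> int:
    n = 0
    with open(path, "w") as handle:
        for name, residues in records:
            handle.write(f">{name}\n")
            for i in range(0, len(residues), width):
                handle.write(residues[i : i + width] + "\n")
            n += 1
    return n


def write_table(frame: pd.DataFrame, path: str | Path, float_format: str = "%.4f") -> None:
    """Write a table as TSV: header row, tab delimiter, '.' decimal, 4-decimal abundances."""
    frame.to_csv(path, sep="\t", float_format=float_format, index=True)


def read_sample_map(path: str | Path) -> SampleMap:
    """Read a sample map TSV with at least sample_label / sample_type / site columns."""
    return SampleMap(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_map(sample_map: SampleMap, path: str | Path) -> None:
    sample_map.rows.to_csv(path, sep="\t", index=False)


def read_fastq_dir(
    directory: str | Path, sample_map: SampleMap | None = None
) -> list[SequenceRecord]:
    """Read every FASTQ file in a directory (one file per sample).

    Sample labels derive from file names; when a sample map is given every
    label must resolve in it.
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix in (".fastq", ".fq")
    )
    if not paths:
        raise FileNotFoundError(f"no FASTQ files in {directory}")
    records: list[SequenceRecord] = []
    for p in paths:
        label = _default_sample_label(p)
        if sample_map is not None and label not in sample_map:
            raise KeyError(f"sample {label!r} (from {p.name}) not in sample map")
        records.extend(read_fastq(p, sample_label=label))
    return records
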