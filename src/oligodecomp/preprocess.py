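"""Read clean-up: fixed 3' trimming, Phred quality filtering, length
normalization into a positional matrix, and dereplication.

The positional matrix is the substrate of all downstream analysis: once every
read is trimmed to one fixed length, column index is positional homology and
per-column nucleotide composition is well defined without an aligner.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .seqio import SequenceRecord

# byte encoding of the 4+1 alphabet; N sorts last so it never wins a vote
_ALPHABET = b"ACGTN"
_CODE = {c: i for i, c in enumerate("ACGTN")}
_DECODE = np.frombuffer(_ALPHABET, dtype=np.uint8)
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_ALPHABET):
    _ENCODE_LUT[_c] = _i
N_CODE = _CODE["N"]


def encode_residues(residues: str) -> np.ndarray:
    """Encode A/C/G/T/N as uint8 codes 0..4."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if (codes == 255).any():
        bad = sorted({chr(b) for b in raw[codes == 255]})
        raise ValueError(f"residues outside A/C/G/T/N: {bad}")
    return codes


def decode_residues(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable clean-up and clustering parameters.

    Defaults follow the source protocol for 18S amplicons: 20 bp trimmed from
    the forward-read 3' end (100 bp for unmerged reverse reads), Q20 quality
    threshold, a further 10 bp off each end before oligotyping, normalization
    to 320 bp, and de novo clustering at 99 % identity (94.9 % for ITS2).
    """

    forward_trim_3prime: int = 20
    reverse_trim_3prime: int = 100
    min_quality: float = 20.0
    quality_mode: Literal["mean", "min"] = "mean"
    oligo_end_trim: int = 10
    target_length: int = 320
    otu_identity_18s: float = 0.99
    otu_identity_its2: float = 0.949

    def __post_init__(self) -> None:
        for name in ("otu_identity_18s", "otu_identity_its2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.target_length <= 2 * self.oligo_end_trim:
            raise ValueError(
                f"target_length ({self.target_length}) must exceed twice "
                f"oligo_end_trim ({self.oligo_end_trim})"
            )


@dataclass(frozen=True)
class StageReport:
    """Read bookkeeping for one clean-up stage: input = passed + discarded."""

    stage: str
    input_reads: int
    passed: int
    discarded: int

    def __post_init__(self) -> None:
        assert self.input_reads == self.passed + self.discarded


@dataclass
class PositionalMatrix:
    """Equal-length reads stacked into a reads x positions byte matrix.

    Rows keep their read id and sample label; columns are positionally
    homologous by construction.
    """

    codes: np.ndarray  # (n_reads, length) uint8 in 0..4
    read_ids: list[str]
    sample_labels: list[str]

    def __post_init__(self) -> None:
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (reads x positions)")
        if len(self.read_ids) != self.codes.shape[0] or len(self.sample_labels) != self.codes.shape[0]:
            raise ValueError("read_ids / sample_labels must match the number of rows")

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, row: int) -> str:
        return decode_residues(self.codes[row])

    def subset(self, rows: np.ndarray | Sequence[int]) -> "PositionalMatrix":
        rows = np.asarray(rows)
        return PositionalMatrix(
            codes=self.codes[rows],
            read_ids=[self.read_ids[i] for i in rows],
            sample_labels=[self.sample_labels[i] for i in rows],
        )

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "PositionalMatrix":
        records = list(records)
        if not records:
            raise ValueError("cannot build a positional matrix from zero reads")
        length = len(records[0])
        if any(len(r) != length for r in records):
            raise ValueError("all reads must share one length")
        codes = np.stack([encode_residues(r.residues) for r in records])
        return cls(
            codes=codes,
            read_ids=[r.read_id for r in records],
            sample_labels=[r.sample_label for r in records],
        )


@dataclass(frozen=True)
class UniqueSequence:
    """A dereplicated sequence with its total and per-sample observation counts."""

    residues: str
    total_count: int
    sample_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.total_count != sum(self.sample_counts.values()) or self.total_count < 1:
            raise ValueError("total_count must equal the sum of per-sample counts (>= 1)")


def trim_3prime(
    records: Iterable[SequenceRecord], n_bases: int
) -> tuple[list[SequenceRecord], StageReport]:
    """Drop ``n_bases`` from the 3' end of every read (qualities in lock-step).

    Reads of ``n_bases`` or fewer would be emptied and are discarded instead.
    """
    if n_bases < 0:
        raise ValueError(f"n_bases must be >= 0, got {n_bases}")
    kept: list[SequenceRecord] = []
    n_in = 0
    for rec in records:
        n_in += 1
        if len(rec) <= n_bases:
            continue
        end = len(rec) - n_bases
        kept.append(
            SequenceRecord(
                read_id=rec.read_id,
                residues=rec.residues[:end],
                qualities=rec.qualities[:end] if rec.qualities is not None else None,
                sample_label=rec.sample_label,
            )
        )
    return kept, StageReport("trim_3prime", n_in, len(kept), n_in - len(kept))


def quality_filter(
    records: Iterable[SequenceRecord],
    min_quality: float,
    mode: Literal["mean", "min"] = "mean",
) -> tuple[list[SequenceRecord], StageReport]:
    """Remove reads below the Phred threshold.

    ``mode='mean'`` (default) drops reads whose mean Phred score is below the
    threshold; ``mode='min'`` applies the threshold per base. Records without
    qualities are an error.
    """
    if mode not in ("mean", "min"):
        raise ValueError(f"unknown quality mode {mode!r}")
    kept: list[SequenceRecord] = []
    n_in = 0
    for rec in records:
        n_in += 1
        if rec.qualities is None:
            raise ValueError(f"read {rec.read_id!r} carries no quality scores")
        q = np.asarray(rec.qualities, dtype=float)
        score = q.mean() if mode == "mean" else q.min()
        if score >= min_quality:
            kept.append(rec)
    return kept, StageReport("quality_filter", n_in, len(kept), n_in - len(kept))


def remove_chimeras(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], StageReport]:
    """Chimera-removal placeholder: the source protocol delegates this to an
    external tool, so the stage passes everything through and reports itself."""
    return records, StageReport("chimera_removal(skipped)", len(records), len(records), 0)


def to_positional_matrix(
    records: Iterable[SequenceRecord],
    oligo_end_trim: int = 10,
    target_length: int = 320,
) -> tuple[PositionalMatrix, StageReport]:
    """End-trim and length-normalize reads into a positional matrix.

    Each read loses ``oligo_end_trim`` bases from both ends (the low-quality
    extremities), then is truncated from the 3' side to exactly
    ``target_length``. Reads that come out shorter are discarded and counted.
    """
    if target_length <= 0:
        raise ValueError(f"target_length must be positive, got {target_length}")
    if oligo_end_trim < 0:
        raise ValueError(f"oligo_end_trim must be >= 0, got {oligo_end_trim}")
    rows: list[np.ndarray] = []
    ids: list[str] = []
    labels: list[str] = []
    n_in = 0
    for rec in records:
        n_in += 1
        start = oligo_end_trim
        stop = len(rec) - oligo_end_trim
        if stop - start < target_length:
            continue
        window = rec.residues[start : start + target_length]
        rows.append(encode_residues(window))
        ids.append(rec.read_id)
        labels.append(rec.sample_label)
    codes = (
        np.stack(rows) if rows else np.empty((0, target_length), dtype=np.uint8)
    )
    matrix = PositionalMatrix(codes=codes, read_ids=ids, sample_labels=labels)
    return matrix, StageReport("length_normalize", n_in, len(rows), n_in - len(rows))


def dereplicate(matrix: PositionalMatrix) -> list[UniqueSequence]:
    """Collapse identical rows into unique sequences with per-sample counts.

    Sorted by total count descending, ties broken lexicographically by
    residue string, so downstream greedy clustering is order-deterministic.
    """
    buckets: dict[bytes, dict[str, int]] = {}
    for row, label in zip(matrix.codes, matrix.sample_labels):
        per_sample = buckets.setdefault(row.tobytes(), {})
        per_sample[label] = per_sample.get(label, 0) + 1
    uniques = [
        UniqueSequence(
            residues=decode_residues(np.frombuffer(key, dtype=np.uint8)),
            total_count=sum(counts.values()),
            sample_counts=dict(sorted(counts.items())),
        )
        for key, counts in buckets.items()
    ]
    uniques.sort(key=lambda u: (-u.total_count, u.residues))
    assert sum(u.total_count for u in uniques) == matrix.n_reads
    return uniques


def expand(uniques: Iterable[UniqueSequence]) -> list[tuple[str, str]]:
    """Inverse of dereplicate up to read identity: (residues, sample) multiset."""
    out: list[tuple[str, str]] = []
    for u in uniques:
        for sample, count in u.sample_counts.items():
            out.extend((u.residues, sample) for _ in range(count))
    return out
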