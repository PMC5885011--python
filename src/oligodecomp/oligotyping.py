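"""Shannon-entropy oligotype decomposition of a per-taxon positional matrix.

The method: compute per-column Shannon entropy over the aligned reads of one
taxon, pick the information-rich columns (components), and partition reads by
the nucleotides they carry at those components. Groups below an abundance
floor are sequencing noise; the remainder are oligotypes — sub-OTU variants
that can differ by a single nucleotide. Decomposition is refined iteratively:
within each kept group, any remaining column whose entropy still exceeds the
threshold is promoted to a component and the partition is recomputed, until
resolution cannot be improved further.

Entropy is measured in bits (log base 2): 0 for a monomorphic column, 1 for
a balanced biallelic column — the effective ceiling for amplicon data, where
columns are at most biallelic in practice — and 2 at the theoretical uniform
four-nucleotide composition. Columns at or below ~0.2 bits are the empirical
footprint of Illumina substitution noise and are left unselected by the
default threshold.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import N_CODE, PositionalMatrix, decode_residues
from .otu import percent_identity
from .seqio import SampleMap
from .taxonomy import Reference

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class OligotypeConfig:
    """Decomposition parameters.

    entropy_threshold
        Minimum column entropy (bits) for a position to become a component;
        the 0.2-bit default sits at the Illumina noise ceiling.
    max_components
        Cap on the number of components (None = unlimited).
    min_oligotype_fraction / min_oligotype_count
        A group is kept iff its read count reaches
        ``max(min_oligotype_count, min_oligotype_fraction * taxon_total)``.
        The fraction floor must sit above the substitution-error footprint:
        errors at a component position spawn spurious groups at an expected
        fraction of error_rate/3 per alternative base, so the 0.005 default
        cleanly separates error groups from real oligotypes for per-base
        error rates up to ~1.5 %.
    component_order
        Ordering of components inside oligotype labels: by descending
        entropy (ties by ascending position) or by ascending position.
    """

    entropy_threshold: float = 0.2
    max_components: int | None = None
    min_oligotype_fraction: float = 0.005
    min_oligotype_count: int = 10
    component_order: Literal["entropy_desc", "position_asc"] = "entropy_desc"

    def __post_init__(self) -> None:
        if self.entropy_threshold < 0:
            raise ValueError("entropy_threshold must be >= 0")
        if self.min_oligotype_count < 1:
            raise ValueError("min_oligotype_count must be >= 1")
        if not 0 <= self.min_oligotype_fraction < 1:
            raise ValueError("min_oligotype_fraction must be in [0, 1)")

    def abundance_floor(self, taxon_total: int) -> float:
        return max(self.min_oligotype_count, self.min_oligotype_fraction * taxon_total)


@dataclass(frozen=True)
class EntropyProfile:
    """Per-position Shannon entropy (bits) over a positional matrix."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if (self.values < -1e-12).any() or (self.values > 2 + 1e-12).any():
            raise ValueError("entropy values must lie in [0, 2] bits")

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": np.arange(self.values.size), "entropy_bits": self.values}
        )


@dataclass(frozen=True)
class OligotypeGroup:
    """Reads sharing one nucleotide string over the selected components."""

    label: str
    read_ids: tuple[str, ...]
    sample_counts: dict[str, int]
    representative: str

    @property
    def total_count(self) -> int:
        return len(self.read_ids)


@dataclass(frozen=True)
class Decomposition:
    """Result of (possibly refined) oligotype decomposition of one taxon."""

    components: tuple[int, ...]  # label order
    kept: tuple[OligotypeGroup, ...]
    noise: tuple[OligotypeGroup, ...]
    n_bucket_ids: tuple[str, ...]
    taxon_total: int
    iterations: int = 1

    def __post_init__(self) -> None:
        covered = (
            sum(g.total_count for g in self.kept)
            + sum(g.total_count for g in self.noise)
            + len(self.n_bucket_ids)
        )
        if covered != self.taxon_total:
            raise ValueError(
                f"partition does not cover the taxon: {covered} != {self.taxon_total}"
            )


def column_counts(matrix: PositionalMatrix, position: int) -> tuple[dict[str, int], int]:
    """Counts of A/C/G/T at one column, with N tallied separately.

    Returns ``(counts, n_count)``.
    """
    if not 0 <= position < matrix.length:
        raise IndexError(f"position {position} out of range [0, {matrix.length})")
    col = matrix.codes[:, position]
    tallies = np.bincount(col, minlength=5)
    counts = {base: int(tallies[i]) for i, base in enumerate(_BASES) if tallies[i] > 0}
    return counts, int(tallies[N_CODE])


def shannon_entropy(counts: Mapping[str, int]) -> float:
    """Shannon entropy in bits of a nucleotide composition.

    H = -sum p_i log2 p_i over residues with positive count. An empty
    composition (all-N column) is defined as 0 and flagged in the log.
    """
    values = np.array([c for c in counts.values() if c > 0], dtype=float)
    if values.size == 0:
        logger.warning("entropy of an empty (all-N) composition defined as 0")
        return 0.0
    return float(stats.entropy(values, base=2))


def _counts_matrix(codes: np.ndarray) -> np.ndarray:
    """(length, 4) A/C/G/T counts per column; N excluded."""
    length = codes.shape[1]
    counts = np.zeros((length, 4), dtype=np.int64)
    for code in range(4):
        counts[:, code] = (codes == code).sum(axis=0)
    return counts


def entropy_profile(matrix: PositionalMatrix) -> EntropyProfile:
    """Per-position Shannon entropy (bits) of a positional matrix."""
    if matrix.n_reads == 0:
        raise ValueError("cannot profile an empty matrix")
    counts = _counts_matrix(matrix.codes)
    totals = counts.sum(axis=1)
    values = np.zeros(matrix.length)
    ok = totals > 0
    if (~ok).any():
        logger.warning("%d all-N columns; their entropy defined as 0", int((~ok).sum()))
    values[ok] = stats.entropy(counts[ok].T, base=2)
    return EntropyProfile(values=values)


def select_components(profile: EntropyProfile, config: OligotypeConfig) -> list[int]:
    """Positions whose entropy exceeds the threshold, in label order.

    Default ordering is descending entropy (ties by ascending position);
    ``position_asc`` orders by position. Truncated to ``max_components``.
    An empty selection is a valid outcome (monomorphic taxon).
    """
    positions = np.flatnonzero(profile.values > config.entropy_threshold)
    ordered = _order_components(
        [(int(p), float(profile.values[p])) for p in positions], config
    )
    if config.max_components is not None:
        ordered = ordered[: config.max_components]
    return ordered


def _order_components(
    scored: Sequence[tuple[int, float]], config: OligotypeConfig
) -> list[int]:
    if config.component_order == "position_asc":
        return sorted(p for p, _ in scored)
    return [p for p, h in sorted(scored, key=lambda t: (-t[1], t[0]))]


def _representative(codes: np.ndarray, rows: np.ndarray) -> str:
    """Most frequent full-length member sequence; ties go to the
    lexicographically smallest so the choice is deterministic."""
    tally = Counter(codes[r].tobytes() for r in rows)
    best = min(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return decode_residues(np.frombuffer(best, dtype=np.uint8))


def decompose(
    matrix: PositionalMatrix, components: Sequence[int]
) -> tuple[list[OligotypeGroup], list[str]]:
    """Partition reads by their residues at the components.

    Reads carrying N at any component go to the N-bucket (second return
    value, as read ids). Groups are sorted by descending count, ties by
    label. The kept/noise split is applied later by :func:`filter_noise`.
    """
    if not components:
        raise ValueError("empty component list; run select_components first")
    comps = list(components)
    if any(not 0 <= c < matrix.length for c in comps):
        raise IndexError(f"component out of range [0, {matrix.length})")
    sub = matrix.codes[:, comps]
    has_n = (sub == N_CODE).any(axis=1)
    n_bucket = [matrix.read_ids[i] for i in np.flatnonzero(has_n)]
    groups: dict[bytes, list[int]] = {}
    for i in np.flatnonzero(~has_n):
        groups.setdefault(sub[i].tobytes(), []).append(i)
    out: list[OligotypeGroup] = []
    for key, rows in groups.items():
        rows_arr = np.asarray(rows)
        label = decode_residues(np.frombuffer(key, dtype=np.uint8))
        sample_counts = Counter(matrix.sample_labels[i] for i in rows)
        out.append(
            OligotypeGroup(
                label=label,
                read_ids=tuple(matrix.read_ids[i] for i in rows),
                sample_counts=dict(sorted(sample_counts.items())),
                representative=_representative(matrix.codes, rows_arr),
            )
        )
    out.sort(key=lambda g: (-g.total_count, g.label))
    return out, n_bucket


def filter_noise(
    groups: Sequence[OligotypeGroup], config: OligotypeConfig, taxon_total: int
) -> tuple[list[OligotypeGroup], list[OligotypeGroup]]:
    """Split groups into kept oligotypes and noise by the abundance floor.

    A group is kept iff its count reaches
    ``max(min_oligotype_count, min_oligotype_fraction * taxon_total)``
    (>= rule); a lone group holding every read of the taxon is always kept.
    Noise groups are returned, never silently dropped.
    """
    if len(groups) == 1:
        return list(groups), []
    floor = config.abundance_floor(taxon_total)
    kept = [g for g in groups if g.total_count >= floor]
    noise = [g for g in groups if g.total_count < floor]
    return kept, noise


def _group_rows(matrix: PositionalMatrix, group: OligotypeGroup) -> np.ndarray:
    index = {rid: i for i, rid in enumerate(matrix.read_ids)}
    return np.asarray([index[rid] for rid in group.read_ids])


def refine(
    matrix: PositionalMatrix,
    config: OligotypeConfig | None = None,
    max_iterations: int = 100,
) -> Decomposition:
    """Full decomposition with iterative refinement until resolution is
    exhausted.

    Starting from the components of the whole-taxon entropy profile, each
    kept group is re-profiled over its own reads at non-component positions;
    a position still above the entropy threshold joins the global component
    set (so labels stay fixed-length) provided its minor alleles are
    numerous enough to form a group above the abundance floor — a split
    below the floor cannot improve resolution, only relabel noise — and the
    partition is recomputed.
    Iteration stops when no group has a position above threshold or the kept
    partition stops changing; the component set grows monotonically and is
    bounded by the matrix length, so termination is guaranteed.

    A matrix with no column above threshold yields zero components and one
    trivial oligotype containing every read.
    """
    config = config or OligotypeConfig()
    profile = entropy_profile(matrix)
    scored: dict[int, float] = {
        int(p): float(profile.values[p])
        for p in np.flatnonzero(profile.values > config.entropy_threshold)
    }
    iterations = 0
    previous_partition: frozenset[frozenset[str]] | None = None
    while True:
        iterations += 1
        components = _order_components(sorted(scored.items()), config)
        if config.max_components is not None:
            components = components[: config.max_components]
        if not components:
            group = OligotypeGroup(
                label="",
                read_ids=tuple(matrix.read_ids),
                sample_counts=dict(sorted(Counter(matrix.sample_labels).items())),
                representative=_representative(
                    matrix.codes, np.arange(matrix.n_reads)
                ),
            )
            return Decomposition(
                components=(),
                kept=(group,),
                noise=(),
                n_bucket_ids=(),
                taxon_total=matrix.n_reads,
                iterations=iterations,
            )
        groups, n_bucket = decompose(matrix, components)
        kept, noise = filter_noise(groups, config, matrix.n_reads)
        partition = frozenset(frozenset(g.read_ids) for g in kept)
        if partition == previous_partition or iterations >= max_iterations:
            break
        previous_partition = partition
        at_cap = (
            config.max_components is not None
            and len(components) >= config.max_components
        )
        new_positions: dict[int, float] = {}
        if not at_cap:
            non_components = np.setdiff1d(
                np.arange(matrix.length), np.asarray(components)
            )
            floor = config.abundance_floor(matrix.n_reads)
            for group in kept:
                sub = matrix.subset(_group_rows(matrix, group))
                sub_profile = entropy_profile(sub)
                counts = _counts_matrix(sub.codes)
                # a split can only improve resolution if the minor alleles
                # could form a group above the abundance floor
                minor = counts.sum(axis=1) - counts.max(axis=1)
                for p in non_components:
                    h = float(sub_profile.values[p])
                    if (
                        h > config.entropy_threshold
                        and minor[p] >= floor
                        and h > new_positions.get(int(p), -1.0)
                    ):
                        new_positions[int(p)] = h
        if not new_positions:
            break
        scored.update(new_positions)
    return Decomposition(
        components=tuple(components),
        kept=tuple(kept),
        noise=tuple(noise),
        n_bucket_ids=tuple(n_bucket),
        taxon_total=matrix.n_reads,
        iterations=iterations,
    )


def oligotype_table(
    groups: Sequence[OligotypeGroup], sample_map: SampleMap
) -> pd.DataFrame:
    """Per-sample oligotype relative abundances (rows sum to 1; all-zero
    rows flag samples with no reads for the taxon)."""
    labels = [g.label for g in groups]
    frame = pd.DataFrame(0.0, index=sample_map.labels, columns=labels)
    for g in groups:
        for sample, c in g.sample_counts.items():
            if sample not in frame.index:
                raise KeyError(f"sample {sample!r} absent from the sample map")
            frame.loc[sample, g.label] = c
    totals = frame.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("samples with no reads for this taxon: %s", list(frame.index[empty]))
    frame.loc[~empty] = frame.loc[~empty].div(totals[~empty], axis=0)
    frame.index.name = "sample_label"
    return frame


def nearest_reference(
    representative: str, references: Sequence[Reference]
) -> tuple[str, float]:
    """Best percent-identity hit of an oligotype representative against the
    reference panel; identity is a fraction (callers print one-decimal %)."""
    if not references:
        raise ValueError("reference set is empty")
    best_ref, best_identity = None, -1.0
    for ref in references:
        identity = percent_identity(representative, ref.residues)
        if identity > best_identity:
            best_ref, best_identity = ref, identity
    assert best_ref is not None
    return best_ref.ref_id, best_identity
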