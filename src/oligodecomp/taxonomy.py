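"""Best-hit taxonomic assignment against a local reference FASTA, and
sample x taxon relative-abundance community tables.

Assignment is exhaustive best-hit percent identity over a small labelled
reference set — a semantic stand-in for a BLAST search against a curated
database, appropriate because amplicon reference panels here number in the
tens of sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .otu import Otu, percent_identity
from .seqio import SampleMap

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Reference:
    """A labelled reference sequence. The taxon label defaults to the FASTA
    description after the first whitespace, falling back to the id."""

    ref_id: str
    taxon_label: str
    residues: str

    @classmethod
    def from_fasta_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        taxon_override: Mapping[str, str] | None = None,
    ) -> list["Reference"]:
        refs = []
        for description, residues in pairs:
            parts = description.split(None, 1)
            ref_id = parts[0]
            label = parts[1].strip() if len(parts) > 1 else ref_id
            if taxon_override and ref_id in taxon_override:
                label = taxon_override[ref_id]
            refs.append(cls(ref_id=ref_id, taxon_label=label, residues=residues))
        return refs


@dataclass(frozen=True)
class TaxonAssignment:
    otu_id: str
    best_ref_id: str
    taxon_label: str
    identity: float

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 1:
            raise ValueError(f"identity out of [0, 1]: {self.identity}")


def assign_best_hit(
    representative: str,
    references: Sequence[Reference],
    min_identity: float = 0.0,
    otu_id: str = "",
) -> TaxonAssignment | None:
    """Return the reference maximizing percent identity, or None if the best
    hit falls below ``min_identity`` (the OTU is then reported as unassigned).

    Ties are broken by reference order in the file.
    """
    if not references:
        raise ValueError("reference set is empty")
    best: Reference | None = None
    best_identity = -1.0
    for ref in references:
        identity = percent_identity(representative, ref.residues)
        if identity > best_identity:
            best, best_identity = ref, identity
    assert best is not None
    if best_identity < min_identity:
        return None
    return TaxonAssignment(
        otu_id=otu_id,
        best_ref_id=best.ref_id,
        taxon_label=best.taxon_label,
        identity=best_identity,
    )


@dataclass(frozen=True)
class CommunityTable:
    """Samples x taxa relative abundances; every non-empty row sums to 1."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.frame.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("community table has negative abundances")
        sums = values.sum(axis=1)
        ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12)
        if not ok.all():
            bad = list(self.frame.index[~ok])
            raise ValueError(f"rows do not sum to 1 (or 0): {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.columns)


def build_community_table(
    assignments: Mapping[str, TaxonAssignment | None],
    otus: Sequence[Otu],
    sample_map: SampleMap,
    assigned_only: bool = True,
) -> CommunityTable:
    """Aggregate OTU counts into per-sample taxon relative abundances.

    Every OTU must appear in ``assignments`` (None marks it unassigned).
    With ``assigned_only`` (default) the unassigned column is reported but
    excluded from the normalizing denominator, mirroring algal-only
    community fractions.
    """
    counts: dict[str, dict[str, float]] = {s: {} for s in sample_map.labels}
    for otu in otus:
        if otu.otu_id not in assignments:
            raise KeyError(f"OTU {otu.otu_id} has no assignment entry")
        assignment = assignments[otu.otu_id]
        taxon = assignment.taxon_label if assignment is not None else UNASSIGNED
        for sample, c in otu.sample_counts.items():
            if sample not in counts:
                raise KeyError(f"sample {sample!r} carries reads but is absent from the sample map")
            counts[sample][taxon] = counts[sample].get(taxon, 0) + c
    frame = pd.DataFrame.from_dict(counts, orient="index")
    frame = frame.reindex(sample_map.labels).fillna(0.0).astype(float)
    frame = frame.reindex(sorted(frame.columns), axis=1)
    denom_cols = [c for c in frame.columns if not (assigned_only and c == UNASSIGNED)]
    denom = frame[denom_cols].sum(axis=1)
    normalized = frame.copy()
    nonzero = denom > 0
    normalized.loc[nonzero, denom_cols] = frame.loc[nonzero, denom_cols].div(
        denom[nonzero], axis=0
    )
    normalized.loc[~nonzero, denom_cols] = 0.0
    if assigned_only and UNASSIGNED in normalized.columns:
        # report the unassigned fraction relative to total reads, outside the
        # normalized composition
        total = frame.sum(axis=1)
        with np.errstate(invalid="ignore"):
            unassigned_frac = np.where(total > 0, frame[UNASSIGNED] / total, 0.0)
        composition = CommunityTable(normalized.drop(columns=[UNASSIGNED]))
        composition.frame[UNASSIGNED + "_fraction_of_total"] = unassigned_frac
        return composition
    return CommunityTable(normalized)


def composition_columns(table: CommunityTable) -> list[str]:
    """The columns of a community table that form the relative-abundance
    composition (excludes the advisory unassigned-fraction column)."""
    return [c for c in table.frame.columns if not c.endswith("_fraction_of_total")]


def top_taxa_summary(table: CommunityTable, coverage: float = 0.99) -> list[str]:
    """Smallest prefix of taxa (by global mean abundance, descending) whose
    summed global mean abundance reaches ``coverage``."""
    if not 0 < coverage <= 1:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    means = table.frame[composition_columns(table)].mean(axis=0)
    means = means[means > 0].sort_values(ascending=False, kind="stable")
    total = means.sum()
    if total == 0:
        return []
    chosen: list[str] = []
    acc = 0.0
    for taxon, value in means.items():
        chosen.append(str(taxon))
        acc += value
        if acc / total >= coverage - 1e-12:
            break
    return chosen
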