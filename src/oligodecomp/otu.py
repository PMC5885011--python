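"""De novo greedy centroid OTU clustering at a strict identity threshold.

The clusterer is the classic abundance-sorted greedy pass (uclust-style):
sequences are visited in dereplication order and join the first centroid they
match at or above the identity threshold, else found a new OTU. At the 99 %
threshold used for 18S amplicons this merges sequences up to 3 mismatches
over 320 nt into one cluster while splitting anything more divergent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import Align

from .preprocess import N_CODE, UniqueSequence, encode_residues


def _hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    mism = (a != b) | (a == N_CODE) | (b == N_CODE)
    return float((a.size - int(mism.sum())) / a.size)


def _semiglobal_identity(a: str, b: str) -> float:
    # end-gap-free alignment; internal gaps count as alignment columns
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -0.5
    aligner.open_gap_score = -1.5
    aligner.extend_gap_score = -0.5
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython spelling
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aln = aligner.align(a, b)[0]
    top, bottom = aln[0], aln[1]
    cols = len(top)
    start = 0
    while start < cols and (top[start] == "-" or bottom[start] == "-"):
        start += 1
    stop = cols
    while stop > start and (top[stop - 1] == "-" or bottom[stop - 1] == "-"):
        stop -= 1
    if stop <= start:
        return 0.0
    matches = sum(
        1
        for x, y in zip(top[start:stop], bottom[start:stop])
        if x == y and x not in "-N"
    )
    return matches / (stop - start)


def percent_identity(a: str, b: str) -> float:
    """Fraction of identical positions between two sequences, in [0, 1].

    Equal-length inputs are compared position-wise (no alignment; N matches
    nothing, including another N). Unequal lengths fall back to an
    end-gap-free semiglobal alignment where internal gap columns count
    against identity. Symmetric; 1.0 iff the sequences are identical and
    N-free.
    """
    if not a or not b:
        raise ValueError("percent_identity requires non-empty sequences")
    if len(a) == len(b):
        return _hamming_identity(encode_residues(a), encode_residues(b))
    # canonical argument order: co-optimal alignments may differ in match
    # count, so fix the orientation to keep the function symmetric
    if (len(a), a) > (len(b), b):
        a, b = b, a
    return _semiglobal_identity(a, b)


def format_identity(identity: float) -> str:
    """Identity as a one-decimal percent string, the field's reporting convention."""
    return f"{identity * 100:.1f} %"


@dataclass
class Otu:
    """An abundance-sorted greedy cluster with its centroid representative."""

    otu_id: str
    centroid: str
    members: list[UniqueSequence]

    @property
    def total_count(self) -> int:
        return sum(m.total_count for m in self.members)

    @property
    def sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            for sample, c in m.sample_counts.items():
                counts[sample] = counts.get(sample, 0) + c
        return counts


def greedy_cluster(
    uniques: Sequence[UniqueSequence],
    threshold: float,
    assign: Literal["first", "best"] = "first",
) -> list[Otu]:
    """Cluster abundance-sorted unique sequences at an identity threshold.

    Each sequence joins the first (or, with ``assign='best'``, the highest-
    identity) existing centroid with identity >= threshold, else founds a new
    OTU whose centroid it becomes. Deterministic in input order.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if assign not in ("first", "best"):
        raise ValueError(f"unknown assignment mode {assign!r}")
    otus: list[Otu] = []
    lengths = {len(u.residues) for u in uniques}
    if len(lengths) <= 1 and uniques:
        # equal-length fast path: vectorised mismatch counts against all centroids
        length = lengths.pop()
        codes = np.stack([encode_residues(u.residues) for u in uniques])
        centroid_rows: list[np.ndarray] = []
        centroid_matrix = np.empty((0, length), dtype=np.uint8)
        for i, unique in enumerate(uniques):
            seq = codes[i]
            if centroid_rows:
                mism = (
                    (centroid_matrix != seq)
                    | (centroid_matrix == N_CODE)
                    | (seq == N_CODE)
                ).sum(axis=1)
                identities = (length - mism) / length
                hits = np.flatnonzero(identities >= threshold)
            else:
                hits = np.empty(0, dtype=int)
            if hits.size:
                j = int(hits[0]) if assign == "first" else int(hits[np.argmax(identities[hits])])
                otus[j].members.append(unique)
            else:
                otus.append(Otu(f"otu_{len(otus) + 1:04d}", unique.residues, [unique]))
                centroid_rows.append(seq)
                centroid_matrix = np.vstack([centroid_matrix, seq[None, :]])
        return otus
    for unique in uniques:
        identities = [percent_identity(unique.residues, o.centroid) for o in otus]
        hits = [j for j, ident in enumerate(identities) if ident >= threshold]
        if hits:
            j = hits[0] if assign == "first" else max(hits, key=lambda j: identities[j])
            otus[j].members.append(unique)
        else:
            otus.append(Otu(f"otu_{len(otus) + 1:04d}", unique.residues, [unique]))
    return otus


def remove_singletons(otus: Iterable[Otu]) -> tuple[list[Otu], int]:
    """Drop OTUs observed exactly once across the dataset; returns (kept, n_removed)."""
    otus = list(otus)
    kept = [o for o in otus if o.total_count > 1]
    return kept, len(otus) - len(kept)
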