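"""End-to-end pipeline assembly and summary outputs.

Runs clean-up, de novo OTU clustering, best-hit taxonomy, per-taxon read
extraction and oligotype decomposition for the most abundant taxa, writing
TSV tables (community composition, entropy profiles, oligotype abundances,
nearest-reference similarities) plus a JSON manifest with telescoping read
counts for every stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .oligotyping import (
    Decomposition,
    OligotypeConfig,
    entropy_profile,
    nearest_reference,
    oligotype_table,
    refine,
)
from .otu import Otu, greedy_cluster, remove_singletons
from .preprocess import (
    PipelineConfig,
    PositionalMatrix,
    StageReport,
    dereplicate,
    quality_filter,
    remove_chimeras,
    to_positional_matrix,
    trim_3prime,
)
from .seqio import SampleMap, read_fastq_dir, write_fasta, write_table
from .taxonomy import (
    Reference,
    TaxonAssignment,
    build_community_table,
    assign_best_hit,
)

logger = logging.getLogger(__name__)


@dataclass
class TaxonDecomposition:
    taxon_label: str
    n_reads: int
    decomposition: Decomposition
    table: pd.DataFrame
    similarities: pd.DataFrame  # oligotype, ref_id, identity_percent


@dataclass
class RunManifest:
    """Record of one pipeline run: configs, per-stage counts, outputs."""

    pipeline_config: dict
    oligotype_config: dict
    seed: int | None
    stages: list[StageReport]
    n_otus: int
    n_otus_after_singletons: int
    taxon_read_counts: dict[str, int]
    outputs: dict[str, str]
    version: str = __version__

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["stages"] = [dataclasses.asdict(s) for s in self.stages]
        return json.dumps(payload, indent=2)

    def validate(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.passed != nxt.input_reads:
                raise ValueError(
                    f"stage counts do not telescope: {prev.stage} passed {prev.passed} "
                    f"but {nxt.stage} saw {nxt.input_reads}"
                )
        for name, path in self.outputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"manifest lists missing output {name}: {path}")


@dataclass
class PipelineResult:
    manifest: RunManifest
    community_table: pd.DataFrame
    otus: list[Otu]
    assignments: dict[str, TaxonAssignment | None]
    taxa: dict[str, TaxonDecomposition]


def _extract_taxon_matrix(
    matrix: PositionalMatrix,
    otus: Sequence[Otu],
    assignments: Mapping[str, TaxonAssignment | None],
    taxon_label: str,
) -> PositionalMatrix:
    """Rows of the positional matrix whose dereplicated sequence belongs to
    an OTU assigned to the taxon (exact, so counts telescope)."""
    wanted: set[bytes] = set()
    for otu in otus:
        assignment = assignments.get(otu.otu_id)
        if assignment is not None and assignment.taxon_label == taxon_label:
            for member in otu.members:
                wanted.add(member.residues.encode("ascii"))
    rows = [
        i
        for i in range(matrix.n_reads)
        if bytes(bytearray(matrix.sequence(i), "ascii")) in wanted
    ]
    return matrix.subset(np.asarray(rows, dtype=int))


def run_pipeline(
    fastq_dir: str | Path,
    sample_map: SampleMap,
    references: Sequence[Reference],
    pipeline_config: PipelineConfig | None = None,
    oligotype_config: OligotypeConfig | None = None,
    outdir: str | Path = "oligodecomp_out",
    top_taxa: int = 4,
    min_assign_identity: float = 0.90,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full analysis and write all artifacts under ``outdir``.

    Stages: 3' trim -> quality filter -> (chimera stage, skipped) -> length
    normalization -> dereplication -> greedy OTU clustering -> singleton
    removal -> best-hit taxonomy -> community table -> per-taxon oligotype
    decomposition for the ``top_taxa`` most abundant taxa. Deterministic;
    ``seed`` is recorded in the manifest for provenance.
    """
    pipeline_config = pipeline_config or PipelineConfig()
    oligotype_config = oligotype_config or OligotypeConfig()
    if not references:
        raise ValueError("reference set is empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_fastq_dir(fastq_dir, sample_map)  # raises on empty input
    stages: list[StageReport] = []

    records, report = trim_3prime(records, pipeline_config.forward_trim_3prime)
    stages.append(report)
    records, report = quality_filter(
        records, pipeline_config.min_quality, pipeline_config.quality_mode
    )
    stages.append(report)
    records, report = remove_chimeras(records)
    stages.append(report)
    matrix, report = to_positional_matrix(
        records, pipeline_config.oligo_end_trim, pipeline_config.target_length
    )
    stages.append(report)
    if matrix.n_reads == 0:
        raise ValueError("no reads survived clean-up")

    uniques = dereplicate(matrix)
    otus = greedy_cluster(uniques, pipeline_config.otu_identity_18s)
    n_otus = len(otus)
    otus, n_singletons = remove_singletons(otus)
    logger.info("clustered %d OTUs (%d singletons removed)", n_otus, n_singletons)

    assignments: dict[str, TaxonAssignment | None] = {
        otu.otu_id: assign_best_hit(
            otu.centroid, references, min_assign_identity, otu_id=otu.otu_id
        )
        for otu in otus
    }
    community = build_community_table(assignments, otus, sample_map)

    taxon_counts: dict[str, int] = {}
    for otu in otus:
        assignment = assignments[otu.otu_id]
        if assignment is not None:
            taxon_counts[assignment.taxon_label] = (
                taxon_counts.get(assignment.taxon_label, 0) + otu.total_count
            )
    chosen = sorted(taxon_counts, key=lambda t: (-taxon_counts[t], t))[:top_taxa]

    outputs: dict[str, str] = {}

    community_path = outdir / "community_table.tsv"
    write_table(community.frame, community_path)
    outputs["community_table"] = str(community_path)

    assign_frame = pd.DataFrame(
        [
            {
                "otu_id": otu.otu_id,
                "ref_id": a.best_ref_id if a else "",
                "taxon": a.taxon_label if a else "unassigned",
                "identity": a.identity if a else float("nan"),
                "total_count": otu.total_count,
            }
            for otu in otus
            for a in [assignments[otu.otu_id]]
        ]
    )
    assignments_path = outdir / "assignments.tsv"
    assign_frame.to_csv(assignments_path, sep="\t", index=False, float_format="%.4f")
    outputs["assignments"] = str(assignments_path)

    rep_fasta = outdir / "otu_representatives.fasta"
    write_fasta([(o.otu_id, o.centroid) for o in otus], rep_fasta)
    outputs["otu_representatives"] = str(rep_fasta)

    taxa: dict[str, TaxonDecomposition] = {}
    for taxon in chosen:
        taxon_matrix = _extract_taxon_matrix(matrix, otus, assignments, taxon)
        assert taxon_matrix.n_reads == taxon_counts[taxon]
        profile = entropy_profile(taxon_matrix)
        decomposition = refine(taxon_matrix, oligotype_config)
        table = oligotype_table(decomposition.kept, sample_map)
        sims = pd.DataFrame(
            [
                {
                    "oligotype": g.label or "(monomorphic)",
                    "ref_id": ref_id,
                    "identity_percent": round(identity * 100, 1),
                }
                for g in decomposition.kept
                for ref_id, identity in [nearest_reference(g.representative, references)]
            ]
        )
        slug = taxon.replace(" ", "_")
        profile_path = outdir / f"entropy_{slug}.tsv"
        profile.to_frame().to_csv(profile_path, sep="\t", index=False, float_format="%.4f")
        outputs[f"entropy_{taxon}"] = str(profile_path)
        table_path = outdir / f"oligotypes_{slug}.tsv"
        write_table(table, table_path)
        outputs[f"oligotypes_{taxon}"] = str(table_path)
        sims_path = outdir / f"similarity_{slug}.tsv"
        sims.to_csv(sims_path, sep="\t", index=False)
        outputs[f"similarity_{taxon}"] = str(sims_path)
        reps_path = outdir / f"oligotype_representatives_{slug}.fasta"
        write_fasta(
            [(f"{slug}|{g.label or 'all'}", g.representative) for g in decomposition.kept],
            reps_path,
        )
        outputs[f"oligotype_representatives_{taxon}"] = str(reps_path)
        noise_frame = pd.DataFrame(
            [
                {"oligotype": g.label, "total_count": g.total_count}
                for g in decomposition.noise
            ]
        )
        noise_path = outdir / f"noise_{slug}.tsv"
        noise_frame.to_csv(noise_path, sep="\t", index=False)
        outputs[f"noise_{taxon}"] = str(noise_path)
        taxa[taxon] = TaxonDecomposition(
            taxon_label=taxon,
            n_reads=taxon_matrix.n_reads,
            decomposition=decomposition,
            table=table,
            similarities=sims,
        )

    counts_frame = pd.DataFrame([dataclasses.asdict(s) for s in stages])
    counts_path = outdir / "stage_counts.tsv"
    counts_frame.to_csv(counts_path, sep="\t", index=False)
    outputs["stage_counts"] = str(counts_path)

    manifest = RunManifest(
        pipeline_config=dataclasses.asdict(pipeline_config),
        oligotype_config=dataclasses.asdict(oligotype_config),
        seed=seed,
        stages=stages,
        n_otus=n_otus,
        n_otus_after_singletons=len(otus),
        taxon_read_counts=taxon_counts,
        outputs=outputs,
    )
    manifest_path = outdir / "manifest.json"
    manifest.outputs["manifest"] = str(manifest_path)
    manifest_path.write_text(manifest.to_json())
    manifest.validate()
    return PipelineResult(
        manifest=manifest,
        community_table=community.frame,
        otus=otus,
        assignments=assignments,
        taxa=taxa,
    )


def summarize_oligotype_sharing(
    tables: Mapping[str, pd.DataFrame], sample_map: SampleMap
) -> pd.DataFrame:
    """Presence/absence and mean abundance of every oligotype by site.

    ``tables`` maps taxon label -> per-sample oligotype abundance table.
    Returns a long-form frame (taxon, oligotype, site, present,
    mean_abundance); empty input yields an empty frame.
    """
    rows = []
    for taxon, table in tables.items():
        sites = {s: sample_map.site_of(s) for s in table.index}
        for label in table.columns:
            by_site = table[label].groupby(pd.Series(sites))
            for site, values in by_site:
                rows.append(
                    {
                        "taxon": taxon,
                        "oligotype": label,
                        "site": site,
                        "present": bool((values > 0).any()),
                        "mean_abundance": float(values.mean()),
                    }
                )
    return pd.DataFrame(rows, columns=["taxon", "oligotype", "site", "present", "mean_abundance"])
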