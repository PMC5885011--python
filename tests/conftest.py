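"""Shared fixtures.

The transect-scale dataset and the full pipeline run on it are expensive
(~40 k reads), so they are session-scoped and shared by the report-level and
acceptance tests. Small unit fixtures are built inline per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from oligodecomp.preprocess import PositionalMatrix
from oligodecomp.report import run_pipeline
from oligodecomp.seqio import SequenceRecord
from oligodecomp.synth import build_preset, preset_references, simulate_reads


def make_matrix(sequences: list[str], samples: list[str] | None = None) -> PositionalMatrix:
    """Build a positional matrix from plain strings (test helper)."""
    samples = samples or ["s1"] * len(sequences)
    records = [
        SequenceRecord(read_id=f"r{i:04d}", residues=seq, sample_label=sample)
        for i, (seq, sample) in enumerate(zip(sequences, samples))
    ]
    return PositionalMatrix.from_records(records)


@pytest.fixture(scope="session")
def gris_config():
    return build_preset("gris_transect")


@pytest.fixture(scope="session")
def gris_dataset(gris_config):
    return simulate_reads(gris_config)


@pytest.fixture(scope="session")
def gris_references():
    return preset_references("gris_transect")


@pytest.fixture(scope="session")
def gris_pipeline(tmp_path_factory, gris_config, gris_dataset, gris_references):
    """Full pipeline run on the transect preset (shared across tests)."""
    root = tmp_path_factory.mktemp("gris")
    gris_dataset.write(root / "reads")
    result = run_pipeline(
        root / "reads",
        gris_config.sample_map(),
        gris_references,
        outdir=root / "out",
        seed=1,
    )
    return result
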