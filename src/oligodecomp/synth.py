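"""Synthetic amplicon-community generator.

Emulates the statistical structure of a Greenland ice-surface algal
community as seen through merged 18S amplicon reads: one dominant taxon
(~92 % of reads) carrying two haplotypes that differ at a single position of
the 320-nt amplicon and are mixed in site-dependent proportions, several
minor taxa at 0.1-5 %, and i.i.d. substitution sequencing errors whose
per-column entropy footprint stays at or below ~0.2 bits. Reads are emitted
already merged, with a 10-nt 5' pad and 30-nt 3' pad around the amplicon
core so the default clean-up (3' trim, end-trim, length normalization)
recovers exactly the core window.

All sequences and every read are synthetic; ground truth (source haplotype
of each read) is recorded so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import decode_residues, encode_residues
from .seqio import SAMPLE_TYPES, SampleMap, SequenceRecord, write_fastq, write_sample_map
from .taxonomy import Reference

#: seed used to draw preset haplotype and flank sequences, fixed so the
#: ground-truth sequences of every preset are stable across runs
PRESET_SEQUENCE_SEED = 7141

LEAD_PAD = 10
TAIL_PAD = 30

PRESETS = ("gris_transect", "single_taxon", "noise_only")


@dataclass(frozen=True)
class Haplotype:
    """One amplicon-core haplotype of one taxon."""

    taxon_label: str
    variant_label: str
    residues: str

    def __post_init__(self) -> None:
        if set(self.residues) - set("ACGT"):
            raise ValueError(f"haplotype {self.variant_label!r} contains non-ACGT residues")


@dataclass(frozen=True)
class SiteProfile:
    """One sample: its site, habitat type, haplotype mixture and read depth."""

    sample_label: str
    site: str
    sample_type: str
    mixing: dict[str, float]
    depth: int

    def __post_init__(self) -> None:
        total = sum(self.mixing.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"sample {self.sample_label!r}: mixing proportions sum to {total}, not 1"
            )
        if any(not 0 <= p <= 1 for p in self.mixing.values()):
            raise ValueError(f"sample {self.sample_label!r}: proportions outside [0, 1]")
        if self.depth < 1:
            raise ValueError(f"sample {self.sample_label!r}: depth must be >= 1")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"sample {self.sample_label!r}: unknown sample type "
                f"{self.sample_type!r} (expected one of {', '.join(SAMPLE_TYPES)})"
            )


@dataclass(frozen=True)
class SynthConfig:
    """Complete recipe for one synthetic dataset.

    ``quality_model`` is the mean Phred score per emitted read position
    (monotone non-increasing toward the 3' end is typical); per-read scores
    jitter around it with ``quality_jitter_sd``. ``flanks`` map each taxon to
    its conserved (5' pad, 3' pad) sequences.
    """

    haplotypes: tuple[Haplotype, ...]
    sites: tuple[SiteProfile, ...]
    error_rate: float
    quality_model: tuple[float, ...]
    seed: int
    flanks: Mapping[str, tuple[str, str]]
    quality_jitter_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.25:
            raise ValueError(f"error_rate must be in [0, 0.25), got {self.error_rate}")
        if not self.haplotypes:
            raise ValueError("config defines no haplotypes")
        if not self.sites:
            raise ValueError("config defines no sites (zero total depth)")
        lengths = {len(h.residues) for h in self.haplotypes}
        if len(lengths) != 1:
            raise ValueError(f"haplotypes have differing lengths: {sorted(lengths)}")
        labels = [h.variant_label for h in self.haplotypes]
        if len(set(labels)) != len(labels):
            raise ValueError("variant labels must be unique")
        known = set(labels)
        for site in self.sites:
            undefined = set(site.mixing) - known
            if undefined:
                raise ValueError(
                    f"sample {site.sample_label!r} mixes undefined variants: {sorted(undefined)}"
                )

    @property
    def amplicon_length(self) -> int:
        return len(self.haplotypes[0].residues)

    @property
    def read_length(self) -> int:
        lead, tail = next(iter(self.flanks.values()))
        return len(lead) + self.amplicon_length + len(tail)

    def haplotype(self, variant_label: str) -> Haplotype:
        for h in self.haplotypes:
            if h.variant_label == variant_label:
                return h
        raise KeyError(variant_label)

    def sample_map(self) -> SampleMap:
        return SampleMap.from_records(
            [(s.sample_label, s.sample_type, s.site) for s in self.sites]
        )


@dataclass(frozen=True)
class SimulatedDataset:
    """Per-sample reads plus the ground truth of every read's origin."""

    config: SynthConfig
    samples: dict[str, list[SequenceRecord]]
    ground_truth: pd.DataFrame  # read_id, sample_label, taxon_label, variant_label

    def haplotype_counts(self, sample_label: str) -> dict[str, int]:
        sub = self.ground_truth[self.ground_truth["sample_label"] == sample_label]
        return sub["variant_label"].value_counts().to_dict()

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write one FASTQ per sample, the ground truth TSV and the sample map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sample, records in self.samples.items():
            path = outdir / f"{sample}.fastq"
            write_fastq(records, path)
            paths[sample] = path
        self.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        write_sample_map(self.config.sample_map(), outdir / "sample_map.tsv")
        return paths


def _random_core(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length).astype(np.uint8)


def _mutate(core: np.ndarray, rng: np.random.Generator, n_subs: int) -> np.ndarray:
    out = core.copy()
    positions = rng.choice(core.size, size=n_subs, replace=False)
    for p in positions:
        out[p] = (out[p] + rng.integers(1, 4)) % 4
    return out


def _with_base(core: np.ndarray, position: int, base: str) -> np.ndarray:
    out = core.copy()
    out[position] = "ACGT".index(base)
    return out


def _quality_ramp(length: int, start: float = 38.0, end: float = 30.0) -> tuple[float, ...]:
    return tuple(np.linspace(start, end, length))


def build_preset(name: str, seed: int | None = None, amplicon_length: int = 320) -> SynthConfig:
    """Return a fully populated preset configuration.

    ``gris_transect``
        The transect scenario: a dominant taxon at 92 % of reads with two
        haplotypes ('A' and 'C' at one amplicon position) mixed 70/30 at
        base-camp-like samples and 30/70 at inland samples, three minor taxa
        at 0.1-5 % whose haplotype sets span 93-100 % mutual identity, and
        0.5 % substitution errors at 10 000 reads per sample.
    ``single_taxon``
        One haplotype, one site, zero error — the noiseless degenerate case.
    ``noise_only``
        One haplotype with 1 % substitution error at depth 10 000: every
        polymorphic column is sequencing noise.

    ``seed`` overrides the preset's documented simulation seed; haplotype
    sequences themselves derive from the fixed ``PRESET_SEQUENCE_SEED``.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available presets: {', '.join(PRESETS)}")
    rng = np.random.default_rng(PRESET_SEQUENCE_SEED)
    L = amplicon_length
    variant_pos = L // 2 - 5  # mid-amplicon, clear of the trimmed ends

    dom_a = _with_base(_random_core(rng, L), variant_pos, "A")
    dom_c = _with_base(dom_a, variant_pos, "C")
    raph = _random_core(rng, L)
    raph_v2 = _mutate(raph, rng, 1)
    raph_v3 = _mutate(raph, rng, 5)
    chlamy_hw = _random_core(rng, L)
    chlamy_dr = _mutate(chlamy_hw, rng, 10)

    flank_pool = {
        taxon: (
            decode_residues(_random_core(rng, LEAD_PAD)),
            decode_residues(_random_core(rng, TAIL_PAD)),
        )
        for taxon in ("Ancylonema", "Raphidonema", "Chlamydomonadaceae_HW", "Chlamydomonadaceae_DR")
    }

    if name == "single_taxon":
        hap = Haplotype("Ancylonema", "Ancylonema_A", decode_residues(dom_a))
        return SynthConfig(
            haplotypes=(hap,),
            sites=(
                SiteProfile("s1_clean_ice", "site_1", "clean_ice", {"Ancylonema_A": 1.0}, 2000),
            ),
            error_rate=0.0,
            quality_model=_quality_ramp(LEAD_PAD + L + TAIL_PAD),
            seed=seed if seed is not None else 101,
            flanks={"Ancylonema": flank_pool["Ancylonema"]},
        )

    if name == "noise_only":
        hap = Haplotype("Ancylonema", "Ancylonema_A", decode_residues(dom_a))
        return SynthConfig(
            haplotypes=(hap,),
            sites=(
                SiteProfile("s1_dirty_ice", "site_1", "dirty_ice", {"Ancylonema_A": 1.0}, 10_000),
            ),
            error_rate=0.01,
            quality_model=_quality_ramp(LEAD_PAD + L + TAIL_PAD),
            seed=seed if seed is not None else 202,
            flanks={"Ancylonema": flank_pool["Ancylonema"]},
        )

    haplotypes = (
        Haplotype("Ancylonema", "Ancylonema_A", decode_residues(dom_a)),
        Haplotype("Ancylonema", "Ancylonema_C", decode_residues(dom_c)),
        Haplotype("Raphidonema", "Raphidonema_v1", decode_residues(raph)),
        Haplotype("Raphidonema", "Raphidonema_v2", decode_residues(raph_v2)),
        Haplotype("Raphidonema", "Raphidonema_v3", decode_residues(raph_v3)),
        Haplotype("Chlamydomonadaceae_HW", "ChlamyHW_v1", decode_residues(chlamy_hw)),
        Haplotype("Chlamydomonadaceae_DR", "ChlamyDR_v1", decode_residues(chlamy_dr)),
    )

    def mixing(dominant_a: float, base_camp: bool) -> dict[str, float]:
        # dominant taxon holds 92 % of the sample; minor taxa split the rest.
        # Raphidonema_v3 (the site-exclusive minor oligotype) occurs only at
        # the base camp.
        m = {
            "Ancylonema_A": 0.92 * dominant_a,
            "Ancylonema_C": 0.92 * (1 - dominant_a),
            "Raphidonema_v1": 0.030 if base_camp else 0.035,
            "Raphidonema_v2": 0.015,
            "Raphidonema_v3": 0.005 if base_camp else 0.0,
            "ChlamyHW_v1": 0.020,
            "ChlamyDR_v1": 0.010,
        }
        assert abs(sum(m.values()) - 1.0) < 1e-12
        return m

    depth = 10_000
    sites = (
        SiteProfile("bc_dirty_ice_1", "base_camp", "dirty_ice", mixing(0.7, True), depth),
        SiteProfile("bc_clean_ice_2", "base_camp", "clean_ice", mixing(0.7, True), depth),
        SiteProfile("s2_dirty_ice_1", "site_2", "dirty_ice", mixing(0.3, False), depth),
        SiteProfile("s3_dirty_ice_1", "site_3", "dirty_ice", mixing(0.3, False), depth),
    )
    return SynthConfig(
        haplotypes=haplotypes,
        sites=sites,
        error_rate=0.005,
        quality_model=_quality_ramp(LEAD_PAD + L + TAIL_PAD),
        seed=seed if seed is not None else 303,
        flanks=flank_pool,
    )


def preset_references(name: str, amplicon_length: int = 320) -> list[Reference]:
    """Synthetic reference panel matching a preset's true haplotype cores.

    For ``gris_transect`` the panel holds one reference per taxon (the 'A'
    haplotype for the dominant taxon, so oligotype 'A' is 100 % identical to
    its reference) plus a near-relative of the 'C' haplotype two mismatches
    away, emulating a congeneric database entry.
    """
    config = build_preset(name, amplicon_length=amplicon_length)
    by_variant = {h.variant_label: h for h in config.haplotypes}
    refs: list[Reference] = []
    if name in ("single_taxon", "noise_only"):
        hap = by_variant["Ancylonema_A"]
        return [Reference("AN_REF1", "Ancylonema", hap.residues)]
    rng = np.random.default_rng(PRESET_SEQUENCE_SEED + 1)
    dom_c = encode_residues(by_variant["Ancylonema_C"].residues)
    relative = _mutate(dom_c, rng, 2)  # 2 mismatches from 'C' -> 99.4 % identity
    refs.append(Reference("AN_REF1", "Ancylonema", by_variant["Ancylonema_A"].residues))
    refs.append(Reference("ME_REF1", "Mesotaenium", decode_residues(relative)))
    refs.append(Reference("RA_REF1", "Raphidonema", by_variant["Raphidonema_v1"].residues))
    refs.append(Reference("HW_REF1", "Chlamydomonadaceae_HW", by_variant["ChlamyHW_v1"].residues))
    refs.append(Reference("DR_REF1", "Chlamydomonadaceae_DR", by_variant["ChlamyDR_v1"].residues))
    return refs


def simulate_reads(config: SynthConfig) -> SimulatedDataset:
    """Draw reads for every sample per its haplotype mixture and error model.

    Per read: a source haplotype is drawn from the sample's mixing
    proportions; the padded full-length sequence is copied and each base is
    substituted independently with probability ``error_rate`` (uniform over
    the three other bases); Phred scores are the quality model plus rounded
    Gaussian jitter, clipped to [2, 40]. Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    model = np.asarray(config.quality_model, dtype=float)
    samples: dict[str, list[SequenceRecord]] = {}
    truth_rows: list[tuple[str, str, str, str]] = []
    for site in config.sites:
        variants = sorted(site.mixing)
        props = np.array([site.mixing[v] for v in variants])
        full_codes = []
        for v in variants:
            hap = config.haplotype(v)
            lead, tail = config.flanks[hap.taxon_label]
            full_codes.append(
                np.concatenate(
                    [encode_residues(lead), encode_residues(hap.residues), encode_residues(tail)]
                )
            )
        full = np.stack(full_codes)
        draws = rng.choice(len(variants), size=site.depth, p=props)
        reads = full[draws].copy()
        if config.error_rate > 0:
            mask = rng.random(reads.shape) < config.error_rate
            shifts = rng.integers(1, 4, size=int(mask.sum()))
            reads[mask] = (reads[mask] + shifts) % 4
        jitter = rng.normal(0.0, config.quality_jitter_sd, size=reads.shape)
        quals = np.clip(np.rint(model[None, :] + jitter), 2, 40).astype(int)
        records: list[SequenceRecord] = []
        for i in range(site.depth):
            read_id = f"{site.sample_label}_r{i:06d}"
            hap = config.haplotype(variants[draws[i]])
            records.append(
                SequenceRecord(
                    read_id=read_id,
                    residues=decode_residues(reads[i]),
                    qualities=tuple(int(q) for q in quals[i]),
                    sample_label=site.sample_label,
                )
            )
            truth_rows.append((read_id, site.sample_label, hap.taxon_label, hap.variant_label))
        samples[site.sample_label] = records
    ground_truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample_label", "taxon_label", "variant_label"]
    )
    return SimulatedDataset(config=config, samples=samples, ground_truth=ground_truth)
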