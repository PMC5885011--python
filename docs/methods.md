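# Methods

## Model and procedure

The pipeline assumes demultiplexed, already-merged amplicon reads (one
FASTQ per sample, Phred+33). Stages, in order:

1. **3′ trimming** — a fixed number of bases (default 20 for forward/merged
   reads; 100 is the conventional figure for unmerged reverse reads) is cut
   from the 3′ end, where Illumina quality decays. Reads shorter than the
   cut are discarded and counted.
2. **Quality filtering** — reads whose mean Phred score falls below Q20 are
   removed. A "minimum Phred score of Q20" rule is ambiguous between a mean
   and a per-base reading; a per-base minimum at Q20 discards nearly
   everything under realistic 3′ quality decay, so the mean reading is the
   default and both are exposed (`quality_mode="mean"|"min"`).
3. **Chimera stage** — a pass-through that reports itself: chimera removal
   belongs to specialised external tools and is out of scope here.
4. **Length normalization** — 10 bp are cut from each end (the error-prone
   extremities), then every read is truncated from the 3′ side to exactly
   320 bp. The result is a *positional matrix*: a gap-free reads × positions
   byte array in which column index is positional homology. All downstream
   math operates on this matrix; coordinates are 0-based, half-open.
5. **Dereplication** — identical rows collapse to unique sequences with
   per-sample counts, sorted by count descending (ties: lexicographic), so
   clustering is order-deterministic.
6. **Greedy OTU clustering** — abundance-sorted first-hit centroid
   clustering: each unique sequence joins the first centroid with identity
   ≥ the threshold (0.99 default; 0.949 for ITS2-like markers), else founds
   a new OTU. Percent identity for equal-length sequences is matching
   positions / length with N matching nothing (including another N —
   conservative, so low-quality reads cannot bridge clusters); unequal
   lengths fall back to an end-gap-free semiglobal alignment in which
   internal gap columns count against identity. Singleton OTUs (one read
   dataset-wide) are removed.
7. **Taxonomy** — each OTU centroid takes the reference with maximal percent
   identity from a local labelled FASTA (ties: file order; below the
   identity floor, default 0.90: unassigned). This is exhaustive best-hit
   search, appropriate for curated panels of tens of sequences; it is a
   semantic, not bit-exact, replacement for a database BLAST. Community
   tables normalise per sample over assigned reads; the unassigned fraction
   is reported as a separate advisory column.
8. **Oligotyping** — for each of the top-k most abundant taxa (default 4,
   by assigned read count), the reads of its OTUs are extracted exactly
   (counts telescope) and decomposed:
   - per-column Shannon entropy H = −Σ p·log₂p over A/C/G/T counts (N
     excluded from the denominator);
   - positions with H > 0.2 bits become components;
   - reads are partitioned by their bases at the components (reads with N
     at any component go to a separate N-bucket);
   - groups below the abundance floor `max(min_count, min_fraction ×
     taxon_reads)` are set aside as noise — reported, never silently
     dropped; a lone group holding every read is always kept;
   - **refinement**: each kept group is re-profiled over its own reads at
     non-component positions; a position above the threshold is promoted to
     the (global) component set only if its minor-allele count could reach
     the abundance floor — a split that cannot yield a keepable group does
     not improve resolution, it only relabels noise. Iteration stops when
     nothing is promoted or the kept partition stops changing; the
     component set grows monotonically and is bounded by the matrix length,
     so termination is guaranteed.
   - oligotype labels are the component nucleotides, components ordered by
     descending entropy (ties: ascending position; `position_asc`
     available). Because components are global per taxon, all labels share
     one length.

Everything is deterministic: no stage draws random numbers, and the
simulator is fully seeded.

## Why bits, and why 0.2

Entropy is computed in log base 2. Amplicon columns are effectively at most
biallelic in practice, so observed values live on a 0–1 scale (1 bit =
balanced biallelic); the theoretical maximum is 2 bits at uniform four-base
composition. Empirically, i.i.d. substitution errors at ~1 % leave
per-column entropy near 0.1 bits at depth 10⁴ (a 99/0.33/0.33/0.33
composition gives H ≈ 0.097; the package's acceptance script measures the
99-of-100 replicate ceiling at ≈ 0.115 bits), so 0.2 bits is a conservative
noise ceiling for component selection.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `forward_trim_3prime` | 20 | bp | 3′ quality decay of merged/forward reads |
| `reverse_trim_3prime` | 100 | bp | heavier decay of reverse reads (unused for merged input) |
| `min_quality` | 20 | Phred | conventional Q20 floor; mean-mode by default |
| `oligo_end_trim` | 10 | bp | error-prone read extremities |
| `target_length` | 320 | bp | fixed amplicon window; defines positional homology |
| `otu_identity_18s` | 0.99 | fraction | strict threshold needed for closely related algal 18S |
| `otu_identity_its2` | 0.949 | fraction | ITS2 convention for algal/fungal communities |
| `entropy_threshold` | 0.2 | bits | substitution-noise ceiling (above) |
| `min_oligotype_count` | 10 | reads | absolute floor against rare error combinations |
| `min_oligotype_fraction` | 0.005 | fraction of taxon reads | must exceed the error footprint: substitutions at a component spawn spurious groups at expected fraction ε/3 per alternative base, so 0.5 % separates error groups from real oligotypes for ε up to ~1.5 % |
| `min_assign_identity` | 0.90 | fraction | taxonomy floor; below it an OTU is reported unassigned |

## The synthetic generator

`oligodecomp.synth` emulates the statistical structure of a glacier-surface
algal community: the `gris_transect` preset draws, per sample, 10 000 reads
from a mixture in which one taxon holds 92 % of the depth via two
haplotypes one nucleotide apart (70/30 at base-camp-like samples, 30/70
inland), three minor taxa share the rest at 0.1–5 % (their haplotype sets
span 93–100 % mutual identity, so the 99 % OTU threshold is exercised in
both directions, and one minor variant is seeded only at the base camp),
and every base is substituted independently with probability 0.005 (uniform
over the other three bases). Reads are emitted merged at 360 nt — a 10-nt
5′ pad and 30-nt 3′ pad around the 320-nt core — so the default clean-up
recovers exactly the core window. Qualities follow a monotone 38→30 ramp
with Gaussian jitter (σ = 2, clipped to [2, 40]). Haplotype and flank
sequences derive from a fixed sequence seed so ground truth is stable;
all sampling uses the config seed, and a fixed seed reproduces the dataset
byte for byte. Per-sample depth (10 000) and the error rate (0.5 %) are
desk-scale stand-ins chosen once as realistic for Illumina amplicon runs.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: indels (the decomposition assumes substitutions
only; real homopolymer indels would break positional homology), chimeras,
PCR and primer bias, position-dependent or motif-dependent error rates,
quality-correlated errors (simulated errors are independent of the
simulated quality string), and paired-end merge artifacts.

## Numerical choices and degenerate inputs

- All-N columns have entropy defined as 0 and are flagged in the log.
- Dereplication and decomposition tie-breaks are lexicographic; group
  representatives are the most frequent full-length member sequence (ties:
  lexicographically smallest).
- Co-optimal semiglobal alignments can differ in match count, so
  `percent_identity` canonicalises argument order to stay symmetric.
- A taxon whose matrix has no column above threshold yields zero components
  and one trivial oligotype covering every read.
- Empty samples produce all-zero table rows and are flagged, never dropped.
- Community-table rows must sum to 1 (±1e-9) or be all-zero; violated
  invariants raise rather than warn.

## Design choices made where the design was open

- **Greedy first-hit clustering** (uclust-style) is the concrete clusterer;
  at 99 % on near-identical amplicons the partition is robust to the
  heuristic, which the oracle-equivalence tests check on small random
  instances. Best-hit assignment is available (`assign="best"`).
- **Mean-quality reading of Q20** (see stage 2).
- **Refinement promotes components globally** so labels stay fixed-length
  per taxon; the promotion guard ties "resolution could not be further
  improved" to the abundance floor (see stage 8).
- **Noise groups are reported, not reassigned.** Merging noise reads into
  kept groups by minimal Hamming distance is possible but blurs the
  kept/noise boundary; abundance estimates here are computed over kept
  groups only.
- **Entropy-exhaustion stop rule**: refinement stops on entropy/floor
  exhaustion rather than on any taxonomic criterion.

## Known limitations

- Identity search is exhaustive (O(centroids × uniques)); fine for desk
  scale and curated reference panels, not for Silva-scale databases.
- Length normalization truncates from the 3′ side; reads shorter than the
  target window are discarded rather than padded or aligned.
- No indel handling anywhere downstream of the positional matrix.
- Best-hit taxonomy has no e-value model; identity ties are broken by file
  order.
- The pipeline's per-taxon read extraction inherits any OTU-level
  mis-assignment; with distant references larger fractions of reads would
  be left unassigned and excluded from decomposition.
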