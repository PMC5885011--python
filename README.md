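# oligodecomp

Shannon-entropy oligotype decomposition of marker-gene amplicon communities,
with strict de novo OTU clustering and a synthetic community generator.

## The problem

Glacier-surface algal blooms darken bare ice and accelerate melt, yet their
communities look almost monotypic through standard amplicon analysis: on the
Greenland Ice Sheet a single zygnematalean alga can account for over 90 % of
18S rRNA reads. Sequences that differ by one nucleotide over a ~320-nt
amplicon are 99.7 % identical, so even an unusually strict 99 % OTU
threshold merges them into one cluster — and any ecological structure
carried by those single-base variants is invisible.

Oligotyping recovers that structure. After reads are trimmed to a fixed
length so that column index equals positional homology, the Shannon entropy
of each alignment column

&nbsp;&nbsp;&nbsp;&nbsp;*H* = −Σᵢ *p*ᵢ·log₂ *p*ᵢ&nbsp;&nbsp;&nbsp;&nbsp;(*p*ᵢ = frequency of base *i* ∈ {A,C,G,T} in the column)

measures how informative that position is: 0 bits for a monomorphic column,
1 bit for a balanced biallelic column, 2 bits at the (unrealistic) uniform
four-base composition. Illumina substitution errors leave an entropy
footprint of roughly 0.1–0.2 bits per column, so columns above ~0.2 bits
carry genuine variation. Reads are partitioned by the bases they hold at
these high-entropy *components*; each partition class is an **oligotype**,
named by its component nucleotides. Decomposition is refined iteratively —
each oligotype is re-profiled and any remaining informative column is
promoted — until resolution cannot be improved further.

The package implements the surrounding pipeline too: 3′ trimming, Phred
quality filtering, length normalization, dereplication, abundance-sorted
greedy OTU clustering at a configurable identity (99 % default for 18S,
94.9 % for ITS2), singleton removal, best-hit taxonomy against a local
reference FASTA, and per-sample relative-abundance tables. A synthetic
generator (`oligodecomp.synth`) emulates the ice-algal data structure with
recorded ground truth, so every stage is testable at desk scale without
external data.

## Worked example

`examples/04_transect_pipeline.py` simulates a four-sample ice-sheet
transect (10 000 reads/sample, 0.5 % substitution error) and runs the full
pipeline:

```
dominant taxon: 32085 reads, 308 OTUs dataset-wide, yet 2 oligotypes at component position(s) [155]

per-sample oligotype abundances (note the base-camp vs inland flip):
                    A      C
bc_dirty_ice_1  0.734  0.266
bc_clean_ice_2  0.720  0.280
s2_dirty_ice_1  0.326  0.674
s3_dirty_ice_1  0.337  0.663

nearest references (one-decimal percent identity):
oligotype  ref_id  identity_percent
        A AN_REF1             100.0
        C AN_REF1              99.7
```

The dominant taxon's two haplotypes — one nucleotide apart, hence a single
99 %-OTU — are recovered as oligotypes 'A' and 'C' at exactly the simulated
variant position (155). Their abundances match the configured 70/30 vs
30/70 site-dependent mixture, the majority oligotype flips between
base-camp and inland samples, and oligotype 'A' is 100 % identical to its
reference while 'C' sits at 99.7 % — the one-mismatch signature.

The other examples are self-contained single-capability walkthroughs:
simulation (`01`), the entropy noise floor (`02`), identity arithmetic and
greedy clustering (`03`).

A thin CLI wraps the library for shell use:

```bash
oligodecomp simulate --preset gris_transect --outdir data/
oligodecomp run --input data/ --sample-map data/sample_map.tsv \
    --refs data/references.fasta --outdir out/
```

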