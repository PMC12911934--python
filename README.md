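# magfred

Genome-resolved **functional redundancy (FRed)** of microbial communities,
computed from MAG (metagenome-assembled genome) trait tables, sample × MAG
abundance matrices, and metatranscriptomic transcript counts.

For each community the pipeline computes:

- **N** — species (MAG) richness,
- **D** — Gini–Simpson diversity, `1 − Σ pᵢ²`,
- **Q** — Rao's quadratic entropy (functional diversity), `Σᵢⱼ pᵢ pⱼ dᵢⱼ`,
- **U** — uniqueness, `Q / D`,
- **FRed** — functional redundancy, `1 − U`,

where `dᵢⱼ` are pairwise Euclidean trait dissimilarities scaled so the
maximum observed distance is 1. FRed is 1 when all members carry identical
traits and 0 when all members are maximally functionally distinct.

Two modes are supported: **potential** FRed from gene presence in genomes
(annotation hit tables, optionally completeness-normalized) and
**expressed** FRed from TPM-normalized transcript counts. Trait subsets
(energy, substrate, CO/H₂/N/S modules, CAZymes) can be analyzed separately;
illustrative subset definitions ship with the package and can be overridden.
A comparative-statistics layer provides Wilcoxon rank-sum contrasts with
Cliff's δ, Pearson correlations, OLS models with a collinearity pre-screen,
and a seeded permutation PERMANOVA. A synthetic-data module generates
guild-structured communities with known closed-form FRed, covariate-driven
abundances, and partially silenced transcript read-outs, so the whole
pipeline is testable without external data.

## CLI

All tables are UTF-8 TSV with a header row; samples are rows and features
are columns.

```bash
# seeded synthetic inputs (hit table, metadata, abundances, transcripts, truth)
magfred simulate --seed 1 --out-dir sim/

# completeness-normalized trait table from raw annotation hits
magfred build-traits --hits sim/hit_table.tsv --mag-metadata sim/mag_metadata.tsv \
    --min-completeness 70 --out traits.tsv

# potential FRed per sample and trait subset
magfred fred --traits sim/hit_table.tsv --abundance sim/abundance.tsv --out fred.tsv

# expressed FRed from transcript counts (TPM)
magfred expressed-fred --transcripts sim/transcripts.tsv \
    --abundance sim/abundance.tsv --out expressed.tsv

# contrasts, FRed ~ environment model, PERMANOVA
magfred stats --fred-results fred.tsv --sample-metadata sim/sample_metadata.tsv \
    --traits sim/hit_table.tsv --abundance sim/abundance.tsv \
    --seed 7 --out-dir stats/
```

Each subcommand also accepts `--config <yaml>` (see `magfred.config.DEFAULTS`
for the recognized keys); flags override config values. `-v`/`-vv` raises
log verbosity on stderr.

## Package layout

- `magfred.io` — TSV readers/writers, validation, MAG quality filter
- `magfred.traits` — completeness normalization, trait subsetting, seasonal log₂ fold changes
- `magfred.redundancy` — trait distances, Gini–Simpson, Rao's Q, FRed
- `magfred.expression` — TPM normalization, expressed trait tables, expressed FRed
- `magfred.stats` — Wilcoxon/Cliff's δ, Pearson, OLS, PERMANOVA
- `magfred.simulate` — seeded guild-structured community simulator
- `magfred.cli` — `magfred` entry point
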