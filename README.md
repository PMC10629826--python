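# bfatools

Analysis toolkit for **double-barcode lineage tracking** and **pooled bulk
fitness assays (BFAs)** in experimentally evolving microbial populations.

In these experiments, hundreds of thousands of yeast lineages carry two DNA
barcodes — a low-complexity *environment barcode* recording which condition a
lineage evolved in, and a high-complexity *lineage barcode* identifying a
single founding cell's descendants. After evolution under serial batch
transfer, clones are re-pooled with a spiked-in ancestor and competed in many
environments; amplicon sequencing of the barcode locus over a handful of
timepoints turns frequency trajectories into per-generation selection
coefficients. `bfatools` implements the full computational path:

1. **Synthetic data** (`bfatools.simulate`) — lineages under exponential
   selection with multinomial bottlenecks and read sampling, raw paired-end
   amplicon reads with UMIs, substitution errors, PCR duplicates, chimeric
   barcode pairs, and GC-content depth bias; the ground truth is retained so
   every downstream stage is testable without external data.
2. **Extraction** (`bfatools.extraction`) — inline-index demultiplexing, a
   one-error-tolerant fuzzy-flank regular expression capturing 24–28 bp
   barcodes, a mean-Q30 quality filter over the barcode region, and
   per-library UMI deduplication (UMI = first 8 bases of each mate).
3. **Error correction** (`bfatools.clustering`) — deletion-neighborhood
   clustering: barcodes whose single-base-deletion sets overlap are one edit
   apart; within each connected component, *peaks* (true barcodes) are called
   by count and edit-distance criteria and every other member folds into the
   nearest peak by Levenshtein distance (≤ 3) or is discarded, with exact
   read conservation. Corrected (environment, lineage) pairs become
   *centroids*; lane intersection and a 100×-imbalance rule remove
   lane-specific contamination and PCR chimeras.
4. **Filters** (`bfatools.filters`) — exclusion of barcodes whose minimum
   26 bp-window GC content is below 4, manual timepoint exclusion, and
   sub-pool-based home-environment assignment (≥ 3 reads, > 95 % in one
   sub-pool).
5. **Fitness inference** (`bfatools.fitness`) — for each lineage the slope of
   ln(frequency) per generation between consecutive valid timepoints
   (≥ 10 reads at both ends), centered by the per-pair **median slope of a
   putatively neutral class** (with iterative merging of low-count neutral
   lineages), averaged into

   ```
   ŝ = mean_k (slope_k − neutral_median_k),   se = SD/√n
   ```

   and combined across replicates by inverse-variance weighting.
6. **Mutation curation** (`bfatools.mutations`) — downstream filtering of
   externally called variants (mitochondrial, *FLO1/FLO9*, clone coverage,
   condition-level background fraction > 12 %, quality < 150, heterozygous
   ref:alt > 3:1 contamination flag), recurrence-based adaptive-gene
   identification, spectrum tabulation, and haploid/diploid overlap. A
   packaged fixture transcribes the curated adaptive-mutation lists for
   clotrimazole (CLM), fluconazole (FLC4) and glycerol/ethanol (GlyEtOH) at
   both ploidies.
7. **Pleiotropy** (`bfatools.pleiotropy`) — fitness profiles across assay
   environments, noise-scaled effect classification (|ŝ| > 2·se),
   pleiotropy-presence and cost-free-adaptation calls, and a permutation test
   for whether same-gene mutations have more similar profiles than
   different-gene mutations.

## Worked example

Simulate a 50-lineage pool (10 neutral) over 5 timepoints of 8 generations at
10⁶ reads per timepoint, in duplicate, and recover the selection
coefficients:

```python
import numpy as np
import bfatools as b

cfg = b.SimulationConfig(
    n_lineages=50, n_neutral=10,
    fitness_distribution={"name": "uniform", "low": -0.1, "high": 0.2},
    n_timepoints=5, read_depth=10**6, bottleneck_size=10**5,
    n_replicates=2, seed=7,
)
truth, counts = b.simulate_pool(cfg)
neutral = {(r.env_bc, r.lineage_bc) for r in truth.lineages.itertuples() if r.neutral}
counts = counts.groupby(["env_bc", "lineage_bc", "timepoint", "replicate"],
                        as_index=False)["count"].sum()
fits = b.estimate_fitness_table(counts, neutral)
combined = fits[fits["replicate"] == "combined"].merge(
    truth.lineages, on=["env_bc", "lineage_bc"])
err = combined["s_hat"] - combined["s"]
print(combined[["lineage_bc", "s", "s_hat", "se", "n_pairs"]].head(5).round(4))
print(f"RMSE over {len(combined)} lineages: {np.sqrt((err**2).mean()):.4f}")
```

prints

```
                lineage_bc       s   s_hat     se  n_pairs
AAATTAGATAGAGTGCTCTTCGTAAC -0.0811 -0.0833 0.0112        8
AACACGGAAGGTTCACTCTGGAGCTA  0.0397  0.0388 0.0020        8
AACTGAGCTTTGAGCTACTGATCGGG -0.0357 -0.0430 0.0034        8
AAGCGCAACTCCGTCGCGCGGGTAGC  0.1216  0.1171 0.0020        8
ACTCACAACCAGCATACATCTTAAAA  0.1768  0.1729 0.0024        8
RMSE over 50 lineages: 0.0049
```

`s` is the true per-generation selection coefficient, `ŝ` the neutral-scaled
estimate and `se` its standard error; `n_pairs` counts the timepoint pairs
that entered the estimate across both replicates.

The same stages are available from the shell:

```bash
bfatools simulate --out run/            # counts, truth, FASTQ reads
bfatools extract  --r1 run/reads_R1.fastq --r2 run/reads_R2.fastq \
                  --index-table run/index_table.json --out run/obs.tsv
bfatools run-all  --out run/            # the whole pipeline with a manifest
bfatools spectrum --out spectrum.tsv    # adaptive-mutation spectrum
bfatools overlap  --out overlap.json    # haploid/diploid gene overlap
```

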