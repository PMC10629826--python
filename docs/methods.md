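# Methods

## Population model

The simulator realizes exponential lineage dynamics under serial batch
transfer. With per-generation selection coefficient `s_i` for lineage `i`
and `Δg` generations per transfer (default 8, matching ~440 generations in
55 transfers), expected frequencies update as

    f_i' = f_i · exp(s_i · Δg) / Σ_j f_j · exp(s_j · Δg)

followed by a multinomial bottleneck of `bottleneck_size` cells and, at each
sequenced timepoint, a multinomial read draw of `read_depth` reads. Both
noise stages are multinomial because serial dilution and sequencing both
sample cells/molecules approximately independently at fixed total; the model
is invariant to adding a constant to every `s` (softmax invariance), which
the tests assert. Neutral lineages have `s = 0` exactly; an optional
ancestor spike-in (9:1 or 4:1 ancestor:pool, the ratios used in the haploid
and diploid assay designs) is a neutral lineage with its own barcodes.

Defaults: 8 generations per transfer and one transfer between sequenced
timepoints, 5 timepoints, bottleneck 10⁵ cells (a desk-scale stand-in for
the ~5·10⁷ cells transferred in the real experiments; configurable), read
depth 10⁶. Barcodes are uniform random A/C/G/T sequences of length 26
(24–28 allowed — the range the extraction pattern accepts).

## Amplicon reads

Each counted read becomes one molecule: two mates, each
`UMI(8) + inline index(6) + pad(10) + GGTACC + barcode + ATAACT + pad(10)`,
with the lineage barcode on read 1 and the environment barcode on read 2
(configurable swap — the amplicon layout is a library-design choice).
Substitution errors hit every base downstream of the inline index at
`base_error_rate`; indel sequencing errors are out of scope. UMI duplicates
re-emit the post-error sequence with the same UMI — i.e. errors are applied
once per molecule, before duplication. Chimeras replace a molecule's
environment barcode with one drawn count-weighted from the pool, modelling
template switching during pooled PCR. Distinct molecules always receive
distinct UMIs within a library (collisions are redrawn), so UMI
deduplication removes exactly the deliberate duplicates.

Left pads are drawn from {A, C, T}. Every left-flank alternative in the
extraction pattern begins with G, so a G-free pad guarantees the leftmost
regex match anchors on the true flank and zero-noise extraction is exact;
with real reads the leftmost-match rule is simply a deterministic
tie-break. Base qualities are constant Q37 — realistic quality-score models
are out of scope, and the Q30 mean-quality filter is exercised in tests with
hand-built reads.

## Extraction

The barcode is group 2 of the fuzzy-flank pattern
`\D*?(GTACC|GGACC|GGTCC|G.TACC|GG.ACC|GGT.CC|GGTA.C|GGTAC.)(\D{24,28})
(.TAACT|A.AACT|AT.ACT|ATA.CT|ATAA.T|ATAAC|AAACT|ATACT|ATAAT)\D*`,
searched over the read portion after the UMI and inline index (the barcode
region plus flanking bases); each alternation tolerates one substitution or
a single-base slip in a flank. Reads are kept when the arithmetic mean
Phred score over the two captured barcode spans is ≥ 30 (a mean of exactly
30.0 passes — the discard rule is "less than 30"). The filter runs after
extraction because it needs the span; reads failing extraction are tallied
separately. Within each library only the first read per 16-base UMI is
kept. Order of operations (filter before dedup) is a design choice; at the
error rates involved it changes only which copy of a duplicate survives.

## Error correction

Observed barcodes form a graph with an edge wherever two sequences'
single-base-deletion sets intersect; deletion sets include the sequence
itself, otherwise sets of different-length sequences could never intersect
and insertion/deletion neighbors would be missed. Self-inclusion also
connects some distance-2 pairs (e.g. adjacent transpositions); this is
harmless because final assignment re-checks true Levenshtein distance.
Connected components ("deletion neighborhoods") are found with a hash index
from deletion string to barcode plus union–find, linear in total deletion-set
size; tests compare it against a naive all-pairs construction.

Within a neighborhood, candidates are visited in descending total count
(lexicographic tie-break, for determinism) and accepted as peaks iff they
contain no `N`, have strictly more than 10 total counts, have no single-edit
neighbor (Levenshtein exactly 1) with more counts, and are more than 3 edits
from every previously accepted peak — so of two equal-count barcodes within
3 edits, the lexicographically smaller becomes the peak. Non-peaks correct
to a peak at distance ≤ 3, preferring higher count; barcodes with no peak
within 3 edits are discarded with their reads tallied (no redistribution
fallback exists). Environment and lineage barcodes are clustered
separately, as their complexities differ by orders of magnitude. Corrected
pairs aggregate into centroids; pairs with ≤ 10 total reads are dropped.
Read conservation (input = centroids + discarded) is exact and asserted.

Lanes are processed independently, then intersected on the full
(environment, lineage) barcode and summed — a combination absent from any
lane is treated as lane-specific contamination. A centroid sharing its
lineage barcode with another centroid under a different environment barcode
with ≥ 100× its reads is removed as a chimera.

Levenshtein distance is the standard two-row dynamic program, cross-checked
in tests against an independent alignment library and a full-matrix
reference DP.

## Filters

GC bias: PCR under-amplifies very AT-rich templates, so barcodes whose
minimum G+C count over a 26 bp sliding window across the concatenated
(environment + lineage) barcode region is below 4 are excluded (exactly 4
is kept). The concatenation is used because the bias acts on the amplicon's
variable region as a whole. Automatic detection of GC-biased timepoints is
not attempted — the package provides a per-timepoint neutral-class
diagnostic table, and exclusions are supplied as a YAML list (empty by
default).

Home environments come from sub-pool sequencing: a barcode is assigned iff
it has ≥ 3 reads and strictly more than 95 % of them in one sub-pool.
Downstream fitness/pleiotropy outputs restrict to lineages assigned to a
configured environment; unassigned lineages are carried with a flag.

## Fitness inference

For each lineage and replicate, frequencies are counts over the
post-filter library total at each timepoint. For each consecutive
timepoint pair where the lineage has ≥ 10 reads at both ends, the slope is
`(ln f_{k+1} − ln f_k)/Δg_k` — per generation, not per cycle. Each slope is
centered by the median slope of the putatively neutral class at that pair
(medians are robust to a few non-neutral contaminants in the class). When
fewer than three neutral lineages are countable at some pair — typical
under strong selection, when the neutral class is being swept out — the two
lowest-total-count neutral lineages are merged (counts summed) repeatedly
until three merged lineages are valid; merging lowest-first preserves the
largest number of usable lineages. Pairs that still fail are unusable
assay-wide. The replicate estimate is the mean of the scaled slopes with
`se = SD/√n` (no `se` when only one pair exists); replicates combine by
inverse-variance weighting, excluding `se`-less replicates, falling back to
a flagged unweighted mean when none has an `se`. Which lineages are neutral
is configuration, not algorithm (in the real assays: haploid YPD clones for
the haploid pool, diploid clotrimazole clones for the combined pool,
timepoint-0 diploid YPD clones for the diploid pool).

## Mutation curation

Variant records from external callers pass, in order: mitochondrial drop;
*FLO1*/*FLO9* drop (poor alignment); clone-coverage floors (10× haploid,
15× diploid); condition-level background drop when a variant appears in
strictly more than 12 % of the clones from one evolution condition;
quality < 150 drop unless whitelisted. Heterozygous variants with
ref:alt > 3:1 are flagged as suspected low-frequency contamination but not
dropped. Human-in-the-loop curation (BAM inspection, repeat-region checks,
BLAST verification) cannot be reproduced from rules and is represented as
explicit keep/drop override lists. A gene is adaptive in a condition iff it
acquired distinct mutations in more than one lineage, the median
home-condition fitness of carriers is > 0, and at least one mutation is
coding; a pathway allowlist admits additionally curated genes.

The packaged fixture (`data/table2_mutations.tsv`) transcribes the curated
adaptive-mutation lists verbatim; effect classes are derived from the
mutation-string dialect (`X123Y` missense, anything containing `*`
nonsense, `_fs` frameshift → coding in/del, multi-residue strings in-frame
indels → coding in/del, `pos REF>ALT` non-coding, `+/` heterozygous
prefix). Row totals equal the printed totals; derived class splits are
consistent with the printed mutation lists, which in a few rows disagree
with the printed class columns. A cross-environment deduplication
convention for a single headline mutation count is not defined by the
rules above and is deliberately not implemented.

## Pleiotropy

Effects classify as beneficial/deleterious when `|ŝ| > k·se` with `k = 2`
(≈95 % two-sided — "within measurement noise" made precise; configurable,
with a fixed-cutoff mode for narrative thresholds). Pleiotropy is present
iff any non-home environment is non-neutral; adaptation is cost-free iff
home is beneficial and no measured non-home environment is deleterious.
The gene-similarity statistic is the mean within-gene pairwise Euclidean
distance over shared measured environments (pairs sharing < 3 environments
are skipped) minus the mean between-gene distance, with a one-sided
permutation p-value (gene labels permuted, +1 correction). The statistic
is our construction; its type-I error is checked by simulation in the test
suite. Collapsing repeated identical mutations to their median profile is
an optional display step.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds; identical
config + seed gives byte-identical outputs (asserted for the pipeline).
The test suite and acceptance script use desk-scale problem sizes chosen to
exercise every rule: fitness recovery uses 120 lineages (100 selected with
s ~ U(−0.2, 0.3), 20 neutral), 5 timepoints × 8 generations, depth 10⁶,
bottleneck 10⁵, 2 replicates; error-correction recovery uses 200 true
26-mers with counts 50–5000 at a 0.005 per-base substitution rate
(~5·10⁵ reads); the zero-noise round trip uses 25 lineages × 3 timepoints
× 4000 reads.

## Known limitations

- Recovery error for strongly deleterious lineages (s ≲ −0.15) is dominated
  by bottleneck drift and read-sampling noise as their trajectories approach
  extinction; their standard errors are correspondingly large, and across
  random seeds the overall recovery RMSE fluctuates around 0.01–0.025.
- The simulator's quality strings are constant; quality-dependent error
  profiles, indel errors, and WGS read simulation are not modelled, so
  passing tests say nothing about those failure modes in real data.
- Error correction is count-based, not quality-aware; directional
  UMI-network methods are out of scope.
- The permutation test assumes profiles are exchangeable across genes under
  the null; correlated measurement noise across environments (e.g. shared
  reference error at a timepoint pair) is not modelled.
- Timepoint exclusion is manual by design: the GC-bias diagnostic table
  supports review but no automatic exclusion is attempted.
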