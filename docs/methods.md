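# Methods

## The scoring model

The score treats regulatory evidence for a SNP as five independent binary
lines, each worth 2 points, summed to an integer in [0, 10]:

* **Chromatin accessibility** — the variant position falls inside at
  least one DNase I hotspot interval, across the union of all loaded
  accessibility tracks (2 points).
* **Histone marks** — overlap with at least one histone-mark ChIP-seq
  broadPeak, any mark, any tissue (2 points).
* **TF binding** — split between positional overlap with a TF motif hit
  (1 point) and the existence of an allele-specific TF-occupancy (CATO)
  record for the rsID (1 point). The two indicators are scored
  independently; jointly they form one line.
* **3D contact** — overlap with an activity-by-contact (ABC)
  enhancer–promoter interaction region (2 points).
* **Expression** — a significant eQTL record for the rsID from any
  configured source; tissue-eQTL-style and blood-cis-eQTL-style tables
  count interchangeably (2 points).

Assumptions built into this model: presence is binary (a variant inside
forty hotspots scores the same 2 points as one inside a single hotspot);
categories are independent in the sense that no interaction terms or
caps apply; and evidence tables are trusted as given — the package never
recomputes CATO, CADD, PhyloP or ABC values, scans motifs, or performs
LD expansion, liftover or colocalization.

### Lookup semantics

Interval files follow the BED convention (0-based, half-open); variant
positions are 1-based, so a variant at position P is stabbed at P−1.
SNPs are 1-bp stabs; indels are tested at their first reference base.
Chromosome names match as exact strings — an optional `normalize_chr`
flag strips the `chr` prefix at load time, and nothing is normalized
silently, so naming mismatches surface as all-zero scores in the
category rather than being papered over.

Table lookups are rsID-keyed (falling back to `chrom:pos[:ref:alt]` keys
for tables without an rsID column). When a table row names alleles and
neither the variant's ref nor alt matches, the row is kept in the details
with an `allele_mismatch` audit flag and still counts toward presence by
default; `strict_alleles` demotes such rows. Multi-allelic inputs are
split into one record per alt; regional evidence is identical across alts
by construction, variant-level lookups run per allele, and the reported
per-rsID score is taken over the union of the alleles' evidence.

Two distinct zero states are distinguished in output: a variant with no
evidence scores 0, and a category with no loaded data contributes 0 to
every variant while being listed in a `categories_missing` column.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| scheme points | 2/2/1/1/2/2 | per-indicator weights; data, not code, so re-weighting needs no code change (`ScoreScheme.validate` enforces the canonical 5×2 structure) |
| `cato_min` | none | minimum CATO score for presence; by default any record counts, since no published cutoff exists |
| `eqtl_min_stat` | none | significance filter for eQTL tables not already restricted to significant associations |
| `min_occupancy` | 10 SNPs | smallest -log10 p bin emitted by GWAS binning |
| `maf_bin_width` | 0.05 | MAF bin for background matching |
| p-value floor | 1e-300 | zero p-values in GWAS input are clamped here |

## Validation statistics

**GWAS binning.** SNPs joining the score map are binned by association
-log10 p in unit-width intervals (default) or nested p-value cutoffs
(`cumulative` mode, matching threshold-style plots). The reported
correlation is Pearson's r between bin rank and mean score (Spearman
optional). At least 3 emitted bins are required; a constant mean-score
profile is reported as an explicit error rather than r = 0.

**MAF-matched background.** For each target SNP one universe SNP is
drawn uniformly without replacement from the same MAF bin, after
excluding target rsIDs; exhausted bins skip the target with a logged
count. The draw is reproducible under a fixed seed.

**emVar enrichment.** Per score bin s, the rate is
1000 · n_set(s) / n_ref(s); bins with an empty reference are omitted.
Two tests are reported. The paired t-test pairs the score-weighted
distribution proportions s·p_set(s) with s·p_ref(s) across populated
bins — the pairing unit is the bin because the two sets differ in size,
and the score weighting makes the mean paired difference equal the
mean-score difference (unweighted proportions would pair to identically
zero). With at most 11 pairs this test is conservative and low-powered;
the Mann-Whitney U on raw per-variant scores is therefore reported
alongside as the assumption-light, higher-powered check. Simulations in
the test suite verify type-I control of both tests under uniform emVar
sampling and ≥80% Mann-Whitney power at 248 emVars drawn ∝ 2^score.

**Credible sets.** Welch's t-test (Mann-Whitney optional) between the
scores of credible-set variants and reported top SNPs, with the
direction of the mean difference reported. Credible sets are consumed
as given; no fine-mapping is performed.

Variants that fail to join the score map are dropped and counted in join
diagnostics in every procedure; nothing is imputed.

## The synthetic generator

The generator plants an exact evidence-flag sextet per variant
(independent Bernoulli per category, default probability 0.5) on a
pseudo-genome of 3 × 10 Mb chromosomes and emits real files: a variant
TSV, one BED/broadPeak track per regional category, CATO/eQTL tables
holding rows exactly for flagged variants, report-only CADD/PhyloP/gene
files, and the truth table. Planting is exact: a true flag gets a
covering interval (length uniform in [150, 2000] bp, a plausible
hotspot/peak scale, with the variant uniformly placed inside); a false
flag is guaranteed uncovered in that category. Variants occupy a slot
grid of pitch 3 × the maximum interval length, so a planted interval
cannot reach a neighbouring variant; decoy intervals (probability 0.5
per false flag) are confined to each slot's leading margin, at least
1 bp clear of every variant position, keeping tracks from containing
only variant-covering features. Placement is checked and retried up to
100 times before erroring, though the grid makes collisions impossible
at the defaults.

The GWAS simulator draws -log10 p = a + b·score + N(0, σ), truncated at
0, with MAF ~ Uniform(0.01, 0.5); b = 0 gives the null. The MPRA
simulator draws emVars without replacement with probability ∝ w^score
via exponential-clocks weighted sampling (w = 1 is the uniform null,
w → ∞ takes only the top populated bin); the tested set is the full
variant list.

All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`, with child streams assigned in a
fixed order (layout, alleles, flags, intervals, decoys, tables, genes),
so regeneration is byte-identical per file and every emitted artifact is
independently reproducible.

What the generator does **not** emulate: LD structure, realistic MAF
spectra or allele-frequency–function coupling, per-tissue track
structure, realistic track density, indels, or genome-scale variant
counts. Passing tests therefore demonstrate the correctness of the
bookkeeping (overlap logic, joins, scoring arithmetic, statistics) under
known truth, not that the score's real-data performance figures
reproduce — those depend on external GWAS/MPRA resources and on binning
details that published summaries do not pin down.

## Numerical and design choices

* Stab queries run on an interval tree; results are sorted by
  (source, start, end, name) with insertion order breaking exact ties,
  so output is invariant to file load order. Identical duplicate
  features are retained, not deduplicated.
* Closest-gene distance is signed: positive when the gene starts
  downstream of the variant, negative when it ends upstream; ties on
  |distance| break by (smaller start, lexicographic name). An empty gene
  track yields a "no gene" sentinel rather than an error.
* Unknown chromosomes in a query return empty results (absence, not
  failure); malformed BED lines and conflicting rsID coordinates are
  hard errors naming the file and line.
* Problem sizes in the test suite: the reference fixture is 2,000
  variants; null-calibration runs use 200 replicates; power runs 100;
  the interval-index oracle check uses 5,000 intervals and ~11,000
  queries. These sizes make every simulated check exact or
  well-converged at desk scale.
* The per-rsID HTML report is rendered from a stdlib string template;
  plots are optional by design — tables are the machine-checked surface,
  figures are presentational.

## Known limitations

* The score is not probabilistically calibrated; 9 vs 10 is a count of
  evidence lines, not a posterior.
* Real-data headline statistics (per-trait correlations, credible-set
  and emVar test p-values from published analyses) are out of reach
  without the original external datasets and their undocumented binning
  choices; the package validates behaviour (calibration, power,
  monotone recovery) instead.
* TF-motif hits and peak files are consumed as-is, with no significance
  or quality filtering.
* eQTL evidence is presence-based and source-agnostic; effect sizes and
  tissues inform the report, never the score.
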