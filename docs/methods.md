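# Methods

`mirslam` quantifies *newly synthesized* mature miRNAs from
nucleotide-conversion sequencing of 4-thiouridine (4SU) metabolic-labeling
experiments, and ships a synthetic study generator with complete ground
truth so that every stage of the pipeline is verifiable offline.

## The measurement model

During 4SU labeling, a fraction of each miRNA's molecules is transcribed
while the label is present ("new" molecules). Chemical derivatization makes
incorporated 4SU read as C instead of T, so a new molecule shows T>C
transitions at a random subset of its uridine positions. For a miRNA *m*
and sample *s*, the pipeline reports

- `read_count` and `cpm` (reads per million assigned),
- `t_coverage`: read-base observations at unmasked reference-T positions,
- `tc_count`: those observations reading C,
- `conversion_rate = tc_count / t_coverage` (defined as 0 when
  `t_coverage = 0`).

Under the generative model used by the simulator, a reference-T position
reads C with probability

    rate = f * p_inc * (1 - e) + (1 - f * p_inc) * e / 3

where `f` is the condition's fraction-new, `p_inc` the probability that a U
in a new molecule yields a detected conversion (incorporation times
chemical-conversion efficiency), and `e` the per-base sequencing-error rate
(errors substitute uniformly among the three alternative bases, hence the
`e/3`). This closed form is the oracle for the recovery tests.

The per-miRNA effect of the drug on synthesis is the background-subtracted
**synthesis ratio**

    ratio = (rate_drug - rate_control) / (rate_vehicle - rate_control)

computed on replicate-mean rates: 1 means synthesis unchanged by the drug,
0 means fully suppressed. Subtracting the no-4SU control removes the
condition-independent background (sequencing error, residual conversions),
and because only a fraction of new molecules carries even one conversion,
the ratio — not the raw rate — is the comparable quantity across miRNAs
with different U content and labeling efficiency. Ratios are not clamped;
values above 1 are reported as-is.

## Study design emulated by the simulator

Three conditions with four replicates each: no-4SU control (vehicle),
4SU+vehicle, and 4SU+drug, mirroring a 4-h labeling experiment with a
splicing inhibitor. Libraries are NEXTflex-style: each read is 4 randomized
nucleotides + insert + 4 randomized nucleotides + 3' adapter, sequenced to
a fixed 75 nt so adapter read-through always occurs (the read length is not
dictated by the protocol; 75 nt is a free choice consistent with a <=100 nt
single-read mode). Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_mirnas` | 50 | desk-scale study; enough units for group analyses |
| `reads_per_sample` | 2e5 | puts per-miRNA counting noise in the regime where the median ratio error is < 0.1 |
| `p_inc` | 0.02 | sub-percent conversion rates as observed for short labeling times |
| `new_fraction_range` | U(0.05, 0.30) | mean 0.175, giving a mean vehicle conversion rate of ~0.35-0.40% |
| `suppression_range` | U(0.2, 1.0) | drug reduces fraction-new per miRNA by a variable factor |
| `frac_unaffected` | 0.1 | a subset of miRNAs is left untouched by the drug, as observed for some loci |
| `seq_error` | 0.001 | Illumina-like substitution floor; contributes ~0.033% to the no-4SU background |
| `expression_sigma` | 1.5 | log-normal abundance, heavy-tailed as in real miRNA libraries |
| u content | U(0.2, 0.45) | typical miRNA U fractions; every sequence is forced to carry >= 1 U |

The generator also plants structural features the filters must handle:
duplicated loci with identical mature sequence (same-context and
mixed-context), miRNAs absent from the curated list, and T>C SNPs at
allele frequency 0.5 or 1.0 (the confounder the SNP mask exists for).
What it does **not** model — isomiR 5'/3' heterogeneity, ligation bias,
PCR duplicates, RNA secondary structure, quality-score variation — means
passing recovery tests demonstrate correctness of the quantification
arithmetic under the stated model, not robustness to every artifact of real
libraries.

## Read processing

Adapter removal finds the longest read suffix matching a prefix of the
adapter (>= 3 bases overlap, <= 10% mismatches); reads without a detectable
adapter are discarded by default, since genuine short-RNA inserts always
read through into adapter. Then 4 bases are clipped from the 3' end, reads
still longer than 30 nt are discarded, 4 bases are clipped from the 5' end,
and inserts shorter than 16 nt are dropped. The `> 30 nt` filter sits
between the two clips, matching a tool chain in which the 3' randomized
bases are removed during adapter trimming and the 5' ones at mapping time.
The 16-nt minimum is our choice (it admits the shortest annotated mature
miRNAs); all values are configurable.

## Conversion-aware assignment

Instead of genome alignment, inserts are compared ungapped against each
mature sequence extended by 3 nt of genomic flank on each side, at every
offset. For mature-miRNA quantification the two are equivalent, and the
feature-space formulation removes the genome dependency; the flank absorbs
templated end variation. Scoring counts a template-T read as C as a match,
so labeling never penalizes assignment, but records it as a conversion.
A read is kept when non-conversion mismatches <= 3 **and** its mapping
integrity (matching fraction) is >= 0.95 — for 21-22-nt inserts the
integrity filter is the binding constraint (two real mismatches already
fail it). Conversions are *not* counted against integrity by default:
penalizing them discards any read carrying >= 2 conversions on a short
insert, which censors the upper tail of the per-read conversion count and
biases the rate estimator low by ~9% at the default operating point. The
strict variant (every non-reference base a mismatch) remains available via
`AlignParams.integrity_counts_conversions`.

Identical mature sequences are collapsed into one counting unit before
alignment, so multi-locus miRNAs are retained at the counting level; a
score tie between units (which always differ in sequence post-collapse)
leaves the read unassigned. Within a unit, the lowest-offset best placement
is taken.

## SNP masking

A germline T>C variant looks like labeling. Reference-T template positions
with pooled coverage >= 10 and alternate-allele fraction >= 0.4 *in the
no-4SU control samples* are masked from both numerator and denominator of
every sample's conversion rate. The 0.4 threshold catches heterozygous
diploid loci (expected fraction 0.5). Calling on controls only — rather
than per sample — guarantees genuine labeling can never mask itself; the
per-sample variant is a documented alternative scope, not implemented as
default.

## Dataset construction

- **Initial dataset**: `cpm > 100` in *every* sample (the per-sample
  reading of "in all datasets") and membership in the curated
  high-confidence list (a collapsed unit qualifies if any member is
  curated).
- **Labeling test**: per unit, conversions vs non-conversions pooled over
  replicates for vehicle and control form a 2x2 table, tested one-sided for
  a higher vehicle rate by the exact conditional (hypergeometric)
  distribution, BH-adjusted across units. `labeled` requires direction
  (vehicle > control) and `p_adj < 0.05`. The published protocol prints the
  significance direction as "`P_adj > 0.05`", which contradicts its own
  "significantly labelled" wording; we implement `<` and surface the
  discrepancy in the membership table's metadata rather than silently
  guessing. Pooled counts (not per-replicate modeling) are a documented
  simplification; replicate variance enters downstream through
  mean-of-rates aggregation.
- **Drug floor**: units whose mean drug-condition rate falls below the
  control mean are excluded (their ratio would be negative noise); the
  boundary case, exactly equal, is retained, giving ratio 0.
- **Context set**: units whose loci or collapsed members span differing
  genomic contexts are excluded from context-grouped analyses only — they
  keep their ratio in the results table.

These sets nest by construction: context set ⊆ Final ⊆ labeled ⊆ Initial.

## Group analyses

Ratios are compared between context groups (intronic vs exonic location,
lncRNA vs protein-coding host, presence/absence of the CNNC, basal UG and
apical UGU Microprocessor-promoting motifs) by Welch's two-sided t-test,
with Mann-Whitney behind a flag because ratio distributions are skewed.
Group summaries report median and 10th/90th percentiles. The five grouped
comparisons are reported without family-wise correction, matching the
single-comparison convention of the emulated analysis; a BH option exists
in the API via `statsmodels`. TSS-distance association uses Spearman rank
correlation (Pearson by flag); a constant variable is defined to return
(rho 0, p 1) rather than NaN. The per-unit x per-sample conversion-rate
matrix feeds a centered, unscaled PCA as a replicate-clustering QC output.

## Numerical and degenerate-input choices

- `conversion_rate` with zero T coverage is 0, and such units are
  untestable in the labeling test (excluded, reason recorded).
- CPM normalizes to 1e6 over assigned reads; with zero assigned reads all
  CPMs are 0.
- BH adjustment spans exactly the testable units.
- Fixed seed implies byte-identical FASTA/BED/TSV/FASTQ outputs; every
  random stream is derived from the single `SimConfig.seed` through
  numpy `SeedSequence` spawning.
- Group comparisons with a group of fewer than 2 units are skipped with a
  warning; TSS correlation requires >= 3 points.

## Verification strategy and problem sizes

The suite checks the implementation against independent oracles: naive
per-offset per-base enumeration for assignment and counting (50 randomized
instances), exhaustive outcome enumeration for the expected-rate formula,
`scipy.stats.fisher_exact` for the labeling test's hypergeometric tail, and
hand-enumerated filter fixtures. Statistical recovery runs at the design
scale (50 miRNAs, 12 libraries x 2e5 reads: median |ratio - truth| < 0.15,
observed ~0.07-0.08) and calibration studies use the model-level simulator
(`simulate_profiles`), which draws the measured quantities directly from
the labeling model so that 200 null studies (suppression = 1) are cheap;
their pooled group-comparison rejection rate sits inside the 95% binomial
band around the nominal 5%.

## Known limitations

- Feature-space assignment cannot discover unannotated miRNAs or isomiRs;
  the curated list and reference are inputs.
- Pooled-count labeling testing understates replicate-level overdispersion;
  with four replicates per condition this is a bias toward liberal
  labeling calls near the threshold.
- The synthesis ratio is undefined for miRNAs whose vehicle labeling does
  not exceed background — such miRNAs (including any whose synthesis the
  drug abolishes entirely while background stays flat) leave the analysis
  at the filtering stage.
- Mean-of-rates replicate aggregation weights replicates equally regardless
  of depth; the pooled-count alternative is available in the API.
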