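# Methods

This note documents the models, filters and numerical choices behind
`edscape`, the assumptions baked into its synthetic-cohort generator, and
what the test suite does and does not establish about real data.

## Biological model

A-to-I editing by ADAR enzymes appears in RNA-seq as A→G mismatches
against the reference on the transcribed strand (reference-forward T→C for
minus-strand genes). Editing concentrates in Alu repeats — inverted Alu
pairs form the double-stranded RNA that ADAR1 prefers — and within
non-coding regions (introns, 3′UTRs), with a characteristic neighbor
preference (5′ U enriched, 5′ G depleted; 3′ G enriched). The analysis
treats the matched DNA as ground truth for the genome: any RNA mismatch at
a known DNA variant position is a genomic variant, not editing, and is
removed unconditionally.

## Coordinates and pileup

All internal coordinates are 1-based inclusive (VCF-style); BED's 0-based
half-open convention is converted at the file boundary in both directions.
The pileup engine streams coordinate-sorted SAM/BAM (via pysam) into
columnar per-observation arrays: base, base quality, mapping quality, read
strand, source read index, and the distance to the **nearer raw-read end**
(computed on the full query sequence, so soft-clipped bases count toward
the distance even though they contribute no aligned observation). Reads
flagged unmapped, secondary, supplementary, QC-fail or duplicate are
excluded; duplicate marking itself is upstream's job. Insertions/deletions
contribute only aligned match positions. N bases, in read or reference,
never count as candidate mismatches. Unsorted input is an error, not a
warning, because every downstream computation assumes position-grouped
observations.

## Site detection

Candidates are positions with ≥ `min_alt_reads` (default 2) observations
of one alternate base passing base quality ≥ 20 and mapping quality ≥ 30,
at total qualifying coverage ≥ 10. The cascade then applies, in order:

1. **DNA-variant exclusion.** Any position present in the sample's DNA
   variant table (germline or somatic SNVs from the VCF) is removed. If no
   table is supplied the filter is skipped with a warning and the output
   header is flagged. This filter is exact by construction — the
   zero-leakage guarantee tested in the suite is a set-membership property,
   not a statistical one.
2. **Read-end artifact rule.** At least one alternate observation must lie
   ≥ 5 bp from the raw read ends; mismatches seen only at read edges are
   characteristic alignment artifacts.
3. **Strand bias.** The alternate reads' forward/reverse split is compared
   with the reference reads' split by Fisher's exact test on the 2×2 table;
   candidates with p < 0.01 are dropped. A one-sample binomial against the
   observed reference strand fraction was considered and rejected: treating
   the noisy reference fraction as a fixed null is miscalibrated at
   realistic depths and discarded ~9% of true sites in simulation, versus
   the nominal ~1% for the two-sample test. With zero reference coverage
   the split is tested against a fair binomial. The test is a per-site
   filter, not an inference, so no multiplicity correction applies.
4. **Simple repeats** (optional, default off): candidates inside a
   user-supplied simple-repeat track can be excluded; the flag is always
   recorded as a feature either way.

Thresholds are deliberately reused from the gene-level read filters (base
quality 20, mapping quality 30) so a site that supports gene-level editing
would also have been callable.

Region classes come from the GTF (`three_prime_utr` and `five_prime_utr`
take precedence over `exon_cds`; exon gaps are introns). A site overlapping
several genes is assigned to all of them for gene-level editing but to a
single canonical gene — longest span, ties broken by gene id — for
catalogs. Sites inside genes on both strands have ambiguous A-to-I
polarity; they are retained but flagged and excluded from all A-to-I
summaries. Intergenic sites infer polarity from the mismatch itself
(A→G ⇒ '+', T→C ⇒ '−').

### Site classifier

A logistic regression (standardized features, lbfgs) over 12 features:
alternate-read count, coverage, frequency, mean alt base quality, mean alt
mapping quality, minimum alt end-distance, strand-bias p, simple-repeat
flag, Alu flag, A-to-I flag, and indicators for 5′ U and 3′ G neighbors on
the transcribed strand. It is trained on the user's own simulation:
candidates extracted with relaxed thresholds (min 1 alt read, no
end-distance or strand-bias gate) are labeled by membership in the planted
truth, which supplies abundant sequencing-error negatives. Training
refuses single-class labels and warns below 50 examples per class;
reported AUC is computed on a stratified 30% holdout. No published
classifier weights are reproduced — the mechanism (features + logistic
confidence + threshold) is the model, and it is retrained per study.

## Editing indices

**AEI.** Numerator: qualifying G observations at transcribed-strand
adenosines inside Alu intervals; denominator: all qualifying observations
at those adenosines, *including* positions with zero mismatches — the
index is activity-weighted by construction, so low-coverage noise cannot
inflate it. Stranded Alu intervals define the transcribed strand;
unstranded intervals contribute reference-forward A→G and reverse T→C
counted separately and summed. Quality cutoffs are the inclusive detection
thresholds (≥ 20 / ≥ 30).

**Region index.** The same ratio restricted to one interval. The MAVS
3′UTR preset (`MAVS_3UTR_hg19`, chr20:3848102-3855844, '+') is stored as a
named region; assemblies are opaque user inputs — the preset is an hg19
interval and it is the caller's responsibility to use hg19-aligned reads
with it.

**Gene-level editing.** For the cohort-filtered A-to-G sites of a gene
(≥ 2 samples, non-intergenic — enforced at the catalog stage, not here), a
read enters the denominator if it covers ≥ 1 listed site with base quality
strictly > 20, mapping quality strictly > 30, and the site ≥ 7 bp from the
raw read ends (the 2 bp-from-trimmed-read rule expressed directly on the
raw read, assuming the conventional 5 bp trim). The numerator counts reads
with ≥ 1 such observation showing the edited base; a read editing two
sites counts once. The result is invariant to site order and duplicates.
An optional `trim_to_length` in the pileup builder supports computing
indices on reads cut to a fixed length (default off).

## Cohort analysis

**Recurrence catalog.** A-to-I genic sites detected in strictly more than
10% of tumor samples (strict inequality on the fraction), detected in zero
controls, and reported in ≥ 2 samples overall. By default every tumor
counts in the denominator whether or not it covers the position — matching
the per-cohort phrasing of the rule; a covered-denominator mode is
available by passing per-sample covered-position sets. Mutation status
uses genic SNVs from the supplied VCFs only (no indels or structural
variants; DNA calling is out of scope).

**Exclusivity.** Per gene, a two-sided Fisher's exact test on the 2×2
table of edited ± × mutated ± over samples; OR < 1 indicates exclusivity.
Degenerate margins (all-true/all-false rows) are flagged and returned as
p = 1, OR = NaN rather than tested. A cohort-wide permutation scheme was
not adopted: the landscape claim is per-gene and qualitative, and the
per-gene test keeps the output interpretable row by row.

**Differential editing.** Replicates are pooled per condition; per genic
adenosine (gene strand resolved from the models; conflicting-strand
positions skipped) a two-sided Fisher's exact test compares
(edited, unedited) counts, Benjamini–Hochberg adjusted within the run.
Gates: *pooled* mode requires ≥ 10 reads per pool in both conditions and
≥ 1 edited read in either; *replicate* mode requires ≥ 50 reads in every
replicate of both conditions and frequency ≥ 0.2 in condition A (the
"wild-type" side by convention — order the arguments accordingly). Gate
attrition is returned so an empty result is always explainable.

**Hyper-editing clusters.** Single-linkage merge of consecutive sites with
inter-site gap ≤ 50 bp (default). 50 bp resolves short hyper-edited runs
separated by unedited stretches at Alu length scales; the value is a
parameter, not a fitted constant.

## Signature scores and statistics

Expression is log2(TPM+1); the transform is flag-guarded so it cannot be
applied twice. A signature score is the mean across-sample z-score of the
member genes (duplicates dropped, zero-variance genes dropped with a
count). This single-sample construction was chosen for reproducibility —
it is fixed, versioned with the package, and invariant to gene order; it
is a documented stand-in wherever an upstream publication's exact score is
not restated. Scores therefore have mean zero across the cohort by
construction and are comparable only within a run. The shipped ISG (38
genes), NF-κB (279) and T-cell-exhaustion (6) lists used by the pipeline's
score stage are synthetic placeholders over simulated gene ids; real
analyses supply their own GMT.

High/low splits label the top 50% high; with odd n the median sample goes
to low (fixed tie rule). Group comparisons use the two-sided Mann–Whitney
U — exact when both groups have ≤ 8 observations and no ties, otherwise
the normal approximation with tie correction. Correlations are Pearson r
with two-sided p; zero-variance input returns NaN rather than raising.
Over-representation is the one-sided hypergeometric tail per gene set,
BH-adjusted across sets within the call. BH is the only multiplicity
procedure in the package and is applied within each analysis family, never
across families.

## Synthetic cohort generator

The generator is the package's study condition, not a tuning knob. Defaults:

| parameter | default | rationale |
|---|---|---|
| cohort | 10 tumors, 4 controls | smallest cohort exercising recurrence fractions |
| genome | 2 × 100 kb, 40 genes | 3-exon genes with 300 bp terminal 3′UTRs |
| planted sites | 1,000 | Alu fraction 0.9, A-to-I fraction 0.95 |
| motif weights | 5′ U 0.60 / G 0.10; 3′ G 0.55 | qualitative ADAR1 neighbor preference |
| activity | tumor mean 1.0, control mean 1/3 (lognormal, σ 0.25) | controls edit, tumors edit ~3× more; the ratio is an assumption, tunable |
| site base frequency | Uniform(0.05, 0.6) | per-sample truth = clip(base × activity, 0, 0.95) |
| tumor-exclusive fraction | 0.3 | gives the recurrence filter true positives |
| reads | 100 bp ungapped, ~30× mean depth | coverage scales per gene with expression |
| errors | 1e-3/base, uniform over the 3 non-template bases | base qualities 37/12 mixture (8% low); mapQ 60/20 (3% low) |
| DNA variants | 200 germline + 20 somatic SNVs/sample | germline on 100% of reads, somatic on 40% |

Reads are emitted directly as aligned SAM records because every
computation in scope starts post-alignment. A `uniform_alu_editing=g` mode
replaces discrete site planting with editing of *every* Alu
transcribed-strand adenosine at frequency g in all samples — the substrate
for AEI parameter-recovery experiments. `simulate_pooled_pair` builds the
minimal two-condition single-gene pools for differential-editing
calibration.

What the generator does **not** emulate: splice junctions and isoforms,
fragment-size structure, batch effects, hyper-edited unmappable reads
(which depress RNA-seq editing estimates in real data), mapping bias, and
non-uniform genome composition. Passing tests therefore demonstrate
correctness of the computations under these idealized conditions — exact
filter semantics, calibrated statistics, parameter recovery — not
robustness to alignment artifacts that real cohorts contain.

## Problem sizes and numerical choices

The test suite and acceptance script run on deliberately compact problem
sizes chosen as the package's own defaults: full-cohort checks use the
default 14-sample/1,000-site configuration (~100 kb of gene territory per
chromosome at 30×); detection-recovery checks average five seeds of a
1-tumor/1-control, 400-site cohort at 40×; AEI recovery uses ≥ 1e5
adenosine observations; differential-editing calibration uses 10 seeds of
100× single-gene pools. Recall/precision checks condition on planted sites
with per-sample frequency ≥ 0.2 and realized coverage ≥ 30, the regime in
which detection is designed to be near-lossless. Floating-point
comparisons in oracle tests are exact on integer counts and tolerance
~1e-9 on p-values; BH q-values are clamped to ≥ raw p.

## Known limitations

- The classifier's feature set (12 features) is a documented subset of the
  feature classes it models; confidence scores are only as good as the
  simulation they were trained on.
- Editing-index confidence intervals are not computed; raw
  numerator/denominator counts are returned instead.
- C-to-U (APOBEC) events are recorded in the mismatch spectrum but not
  called as editing.
- Hyper-edited-read rescue (realignment of heavily edited reads) is out of
  scope; transcriptome-wide indices will underestimate editing on data
  where such reads fail to map.
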