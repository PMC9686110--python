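# Methods

## The measurement model

RNA bisulfite sequencing converts unmethylated cytosine to uracil; m⁵C
resists conversion. After alignment, each reference cytosine under a read
is *converted* (read shows T), *unconverted* (read shows C) or *other*
(mismatch; excluded from both tallies). The library is stranded, so only
sense-strand cytosines are informative; antisense alignments are skipped
and counted, as are non-unique alignments (MAPQ 0, secondary or
supplementary records).

At a site with 3C-passing coverage n and unconverted depth k, the
methylation level is m = k/n. Under the null (no methylation) each
unconverted C is a conversion failure with probability p₀ = 1 − r, where
r is the per-library conversion rate estimated from an unmethylated
spike-in transcript: r = converted / (converted + unconverted) over *all*
spike-in cytosine observations. The 3C filter is intentionally not
applied to the spike-in, so the estimate reflects the library's full
chemistry, incomplete conversions included; this makes p₀ conservative
(slightly too large) for the post-filter read population, which only
reduces false positives. With no spike-in observations the caller falls
back to a configured default rate and says so.

## The filter cascade

The per-site test is the one-sided binomial upper tail
p = P[X ≥ k], X ~ Binomial(n, p₀) — one-sided because methylation can
only inflate unconverted counts. It is computed as a log-space tail sum
(logsumexp of exact log-pmf terms), stable to p ≈ 10⁻³⁰⁰.

Filters, in reporting order (survival is order-independent):

1. **3C filter** (read level): more than 3 unconverted Cs ⇒ the read is
   an incomplete conversion and is removed before pileup counting.
   Unconverted Cs at genuinely methylated positions do count toward the
   threshold — the rule names no exemption — so a read spanning more than
   three fully methylated cytosines would be lost; the simulator
   therefore plants at most one site per read-length window by default,
   and real transcriptomes make this collision vanishingly rare at the
   observed site density (~1 site per methylated transcript).
2. **Standard filter**: n ≥ 20, m ≥ 0.1, k ≥ 6.
3. **Signal/noise filter**: S = coverage_pass / coverage_all > 0.9, i.e.
   more than 90% of reads covering the site survived the 3C filter. The
   published pipelines cite this filter without restating a formula; this
   definition (the obvious read-quality reading) is pluggable.
4. **FDR filter**: BH-adjusted q < 0.05. The BH family is the library's
   candidates with k ≥ 1; structural zeros (k = 0, p = 1 by definition)
   are reported but excluded from the family so they do not dilute the
   correction. Whether the original analyses included them is unstated;
   including them would only make q-values smaller (never larger) for
   k ≥ 1 sites, so this choice is the conservative one.
5. **Structure filter**: sites inside predicted conversion-resistant
   regions are removed. Folding is not re-run here; the filter consumes
   BED intervals or dot-bracket strings (a site is removed iff its
   cytosine is base-paired), and the folding parameters used to produce
   an imported mask belong in the run manifest.
6. **Replicate intersection**: a high-confidence site passes *all*
   filters independently in every biological replicate of a condition
   (being merely covered in the other replicate is not enough). Its level
   is the pooled Σk/Σn across replicates — pooling weights replicates by
   coverage; per-replicate levels are kept alongside.

All coordinates are 0-based half-open internally; SAM I/O converts at the
boundary.

## Differential methylation

For two conditions, replicate counts are pooled within condition and each
eligible site gets a two-sided Fisher's exact test on
[[k_A, n_A−k_A], [k_B, n_B−k_B]]; eligibility requires coverage ≥ 20 in
*every* library involved and high-confidence methylation in at least one
condition. Two-sided p-values sum hypergeometric probabilities ≤ the
observed table's probability (relative tie tolerance 10⁻⁷); zero-margin
tables give p = 1. BH runs across eligible sites; q < 0.05 defines a DMS,
with direction hyper/hypo by pooled level. Pooling replicates before the
2×2 test is a simplification: it ignores between-replicate dispersion,
which a beta-binomial model would capture, but matches a per-site
single-table test and is exact at the counts it sees.

The total-vs-polysome comparison pairs pooled levels at sites that are
high-confidence in either methylome and covered ≥ 20 in both, then runs a
Wilcoxon signed-rank test: zero differences dropped, average ranks for
ties, exact null up to 25 non-zero pairs (when untied), otherwise a
normal approximation with tie correction and continuity correction (as in
R's `wilcox.test`). Both one- and two-sided p-values are reported, the
one-sided alternative being polysome hypermethylation.

## Translation efficiency

TE = (mean normalized polysome count) / (mean normalized total count),
with median-of-ratios size factors (median over all-positive genes of
count / geometric mean). Normalizing jointly across fractions means TE is
relative to the median gene; TE *fold changes* between conditions — the
quantity the 1.2-fold threshold applies to — are invariant to that
constant and to any per-sample rescaling of raw counts.

Significance comes from a self-contained NB Wald engine (the original
analyses used external DE/TE packages; the decision rules and thresholds
are kept, the estimator is this package's own, and agreement with any
specific external tool's gene lists is not claimed):

* per-gene dispersion α by within-replicate-group method of moments,
  (var − mean)/mean² on normalized counts, pooled across groups by
  degrees of freedom;
* a mean–dispersion trend α(μ) = a₀ + a₁/μ fitted by trimmed least
  squares over informative genes (fallback: the median dispersion when
  fewer than 20 genes inform the fit);
* shrinkage of the per-gene estimate toward the trend with 6
  pseudo-degrees of freedom — heavy at 2 replicates by design, since the
  replicate-level estimate has almost no information;
* per-group mean MLE q̂ by Newton iteration on the NB score with
  size-factor offsets; Wald tests on log-mean contrasts, with variance
  from the observed Fisher information. Differential expression uses the
  two-group contrast; differential TE uses the fraction × condition
  interaction (four group fits per gene, all vectorized across genes).

Fold changes are *reported* from pseudocounted normalized means
(log₂((q̂_A + 0.5)/(q̂_B + 0.5))) so zero counts never print infinities;
tests use the raw MLE contrast and genes with an all-zero group are
reported untested. DTGs require mean normalized count ≥ 1
(minMeanCount), |TE fold change| > 1.2 and q < 0.05; the ratio-of-ratios
TE fold change is authoritative for the threshold, the interaction
estimate is reported alongside. Translation classes per condition come
from polysome-vs-total differential expression: up ⇒ high, down ⇒ low,
otherwise (including untested genes) median; the 1.2-fold requirement is
applied by default and can be relaxed to q-only via a flag.

Measured operating characteristics (reproduced by the test suite): on
null 2-vs-2 comparisons of 2,000 simulated genes the Wald p-values reject
at 0.05 in ~6% of genes; planted 4-fold changes at base mean 500 and
dispersion 0.05 are detected in ≥ 95% of runs.

## Integration

Each transcript bearing at least one significant polysome-vs-total DMS
is paired with its translation class: (hyper, high) and (hypo, low) are
*positive* correlation, (hyper, low) and (hypo, high) *negative*, and any
direction with median translation *neutral*. Transcripts with DMS of
opposite directions get one record per direction, flagged ambiguous,
rather than being silently collapsed. Summaries tally both transcripts
and sites (the two can differ when transcripts carry several DMS);
cross-condition consistency requires a record in every condition with all
categories equal.

## The synthetic-data generator

The generator emulates the study conditions: stranded, pre-aligned
single-end reads in transcript coordinate space (the upstream aligner is
out of scope; every computation here operates on aligned reads), with

* per-cytosine conversion probability r = 0.999 for unmethylated Cs;
* planted site levels Beta(2, 8.2) — numeric median 0.196, ~72% of mass
  below 0.3 — matching reported m⁵C level distributions; a configurable
  fraction (default 0.7) of sites has its downstream context rewritten to
  A/G at +1 and GGG at +2..+4;
* a 0.5% mass fraction of reads from an unmethylated 1,850-nt spike-in
  transcript (ID prefix `SPIKE_`);
* 1% incomplete-conversion reads (per-C conversion 0.5 within such
  reads, ground-truth-tagged `:INC` in the read name). Real libraries'
  incomplete fraction is not published; 1% is a simulation knob chosen to
  be visible without dominating;
* mRNA 5′UTR/CDS/3′UTR means 150/900/450 nt (±20% uniform jitter), ~3%
  ncRNA and ~1% pseudogene transcripts, uniform base composition;
* NB count matrices: base means log-normal (median 300, σ = 1.2 in log),
  dispersions log-normal around 0.02 (cell-culture-replicate scale),
  planted expression effects ±U(0.5, 2) log₂ in 10% of genes and TE
  effects ±U(1, 2) log₂ in 10% of genes, per non-reference condition;
  per-sample library sizes log-normal (σ = 0.1). Dispersion 0 is the
  deterministic limit (counts = rounded means) so exact-equality
  contracts are testable.

Sites are planted at least one read length from transcript ends and from
each other: even coverage, full motif flanks, and no read can span two
sites (see the 3C note above). Determinism: every stage draws from
`numpy` generators seeded by (seed, stage salt), so identical configs
give byte-identical FASTA/SAM/BED/TSV outputs.

Deliberately not modeled: sequencing errors by default (a substitution
knob exists), indels, paired-end chemistry, PCR duplicates, fragmentation
bias, RNA degradation, isoform structure. Passing tests on this generator
therefore demonstrate the *statistical* correctness of the cascade and
tests under the stated chemistry model, not robustness to alignment
artifacts or isoform ambiguity.

## Validation experiment sizes

The experiments in `bsm5c.validation` (run by `tests/test_acceptance.py`
and `scripts/acceptance.py`) use: ~10⁵ cytosines × 6 libraries at 50× for
null specificity; 200 planted sites × 2 replicates at 50× for recovery;
one 50×-coverage library with 5% incomplete reads for 3C efficacy; 100
runs (400 for the null size) of 100-site signed-rank comparisons; 100
runs of 50-site DMS null calibration plus a targeted 0.30-vs-0.10 power
check at pooled n = 100; five 2,000-gene count simulations for DTG
recovery; 10⁵ uniform sites for metagene flatness. The signed-rank power
check and DMS power check simulate at the level/count layer directly —
the read-level machinery is already exercised by the recovery and
specificity experiments, and the questions being asked are about the
tests, not the pileups.

## Known limitations

* Transcript-space, one model per gene: no isoform-level resolution.
* Fisher on pooled replicates understates between-replicate variance.
* The signal/noise formula and the BH-family composition are stated
  choices where the published description is not fully explicit; both are
  configurable/pluggable.
* The NB engine is a stand-in estimator: calibrated, but not a
  reimplementation of any external package's shrinkage machinery.
* TE levels are relative (joint normalization); only TE ratios between
  conditions are absolute.
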