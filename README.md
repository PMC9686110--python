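# bsm5c

Calling 5-methylcytosine (m⁵C) sites from RNA bisulfite sequencing and
relating them to mRNA translation.

Bisulfite treatment converts unmethylated cytosines to uracil (read as T),
while m⁵C resists conversion and is still read as C. A cytosine's
methylation level is therefore estimated from aligned reads as
*m = k / n*, the fraction of C calls among reads covering it — but raw
unconverted signal is dominated by artifacts: incomplete bisulfite
conversion of whole reads, secondary structure shielding cytosines from
the chemistry, and sampling noise at the ~0.1% background
conversion-failure rate. `bsm5c` implements the full analysis stack
around this problem for transcript-space alignments:

* **Read processing** — per-read conversion profiles on the sense strand;
  reads with more than 3 unconverted Cs are discarded as incomplete
  conversions (the *3C filter*); the per-library conversion rate *r* is
  estimated from an unmethylated spike-in control (0.5% of library mass),
  giving the null error rate *p₀ = 1 − r*.
* **Site calling** — each covered cytosine is scored with a one-sided
  binomial test, p = P[X ≥ k], X ~ Binomial(n, p₀), BH-adjusted per
  library. A site survives iff n ≥ 20, m ≥ 0.1, k ≥ 6, signal/noise
  (3C-passing fraction of covering reads) > 0.9 and q < 0.05; sites inside
  predicted conversion-resistant structure are removed, and only sites
  passing independently in **both biological replicates** are reported as
  high-confidence, with pooled level Σk/Σn.
* **Profiling** — 5′UTR/CDS/3′UTR annotation, a 5/18/22-bin metagene
  density, ±5 nt sequence-context matrices (m⁵C sites show a downstream
  (A/G)GGG-rich context), and level summaries (median level ≈ 20% in
  published methylomes).
* **Differential methylation** — per-site two-sided Fisher's exact tests
  on pooled (k, n−k) counts between conditions (eligibility: coverage
  ≥ 20 in every involved library, methylated in ≥ 1 condition), BH
  correction, q < 0.05; plus a paired Wilcoxon signed-rank comparison of
  total vs polysome methylomes.
* **Translation efficiency** — TE = polysome/total on normalized counts;
  differential TE via a negative-binomial Wald test on the
  fraction × condition interaction; DTGs at |fold change| > 1.2 and
  q < 0.05 (minMeanCount = 1); per-condition translation classes
  (high/median/low) from polysome-vs-total differential expression.
* **Integration** — transcripts bearing differentially methylated sites
  are classified as *positive* (hyper+high or hypo+low), *negative*
  (hyper+low or hypo+high) or *neutral* (median translation), summarized
  per condition and intersected across conditions.
* **Synthetic data** — a seeded generator for transcriptomes, planted
  m⁵C truth (Beta(2, 8.2) levels), bisulfite read libraries in SAM
  (including spike-in and incomplete-conversion reads), structure masks
  and NB count matrices, so every stage is testable against known truth.

## Worked example

Simulate a three-condition study (100 transcripts, 50 planted m⁵C sites,
two replicates at 50×) and call sites in the LF condition:

```
$ bsm5c simulate --seed 2 --out demo
wrote 101 transcripts, 50 sites -> demo

$ bsm5c call-m5c --fasta demo/transcripts.fa \
    --sam demo/reads_LF_R1.sam --sam demo/reads_LF_R2.sam --out demo/LF
demo/reads_LF_R1.sam: 74269 reads profiled, 760 failed 3C, conversion rate 0.99643
demo/reads_LF_R2.sam: 74269 reads profiled, 791 failed 3C, conversion rate 0.99719
41 high-confidence m5C sites -> demo/LF.sites.tsv

$ head -3 demo/LF.sites.tsv
transcript_id  position  pooled_n  pooled_k  pooled_level  level_R1  level_R2
T00000         316       111       23        0.2072        0.1961    0.2167
T00002         1095      121       41        0.3388        0.3333    0.3443
```

The 101st transcript is the unmethylated spike-in; its reads give each
library's conversion rate (≈0.997 here — slightly below the configured
0.999 because 1% of simulated reads are incomplete conversions, which the
spike-based estimate deliberately includes and the 3C filter later
removes). 41 of the 50 planted sites pass the full cascade in both
replicates; the misses are low-level sites (< ~0.15) that cannot reach
the methylated-depth threshold (k ≥ 6) at 50×. Pooled levels (e.g. 0.207,
0.339) estimate each site's true methylation fraction.

The whole analysis — simulation through methylation × translation
categories — runs end to end with `bsm5c run-all --seed 2 --out run/`,
which writes per-stage TSVs and a `manifest.json` with seeds, thresholds
and output checksums (identical seeds reproduce identical outputs).

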