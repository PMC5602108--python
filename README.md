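# meripeak

Peak calling and near single-nucleotide site detection for MeRIP-seq /
m⁶A-seq experiments.

N⁶-methyladenosine (m⁶A) is the most abundant internal mRNA modification.
m⁶A-seq profiles it by immunoprecipitating methylated RNA fragments with an
anti-m⁶A antibody and sequencing them alongside a matched RNA-seq control
(INPUT): a methylated adenosine shows up as a peak of IP coverage, roughly
twice as wide as the sequenced fragment, enriched over INPUT.  Standard
ChIP-seq callers handle this data poorly (spliced alignments, expression
confounding, mate pairs spanning multi-kilobase introns), enriched regions
from binning-based callers can span kilobases, and m⁶A-seq peak sets carry
many false positives.  `meripeak` addresses all three problems for
bioinformaticians analysing m⁶A-seq data:

* **Fragment-coverage peak calling.**  Per-base coverage is computed from
  inferred RNA *fragments*, not raw reads: mates are joined (overlap counted
  once, annotated introns excluded from the inner-mate gap) and single-end
  reads are extended toward their 3′ end, respecting exon boundaries when a
  GTF is supplied.  Summits are local maxima of the smoothed IP track;
  partially overlapping peaks are split at the summit midpoint.  Each peak
  region is tested with a one-sided Fisher's exact test on the 2×2 table of
  region/library fragment counts (IP vs INPUT), with
  Benjamini–Hochberg/Benjamini–Yekutieli/Bonferroni FDR control and
  enrichment-fold (default 2×), coverage (default 20 fragments) and optional
  replicate-reproducibility filters.
* **EM peak deconvolution.**  Each enriched region is modelled as a mixture
  of fragment-coverage distributions — one component per methylated
  adenosine plus a uniform noise component.  Candidate site positions are
  the region's A's (optionally only RRACH-context A's, R = A/G, H = A/C/U);
  expectation–maximization assigns fragments to sites and relocates sites,
  and the Bayesian information criterion picks the number of sites.  This
  resolves closely spaced sites that merge into one broad peak and places
  single sites far more precisely than the summit alone.
* **False-positive filtering.**  A supervised filter combines a mixture
  transition distribution (MTD) Markov model of the 200-nt peak sequence
  (alphabet A/C/G/T/M, M marking the called site) with a 1000-tree random
  forest over peak features (MTD likelihood ratio, consensus distance,
  k-mer content, enrichment, transcript context).  Training labels come
  from methyltransferase-knockdown pairs: peaks absent after knockdown are
  genuine m⁶A; peaks whose enrichment barely changes are technical
  artefacts.
* **Synthetic data.**  A simulator generates transcripts, planted
  RRACH-context sites, and IP/INPUT BAMs with known ground truth, so the
  entire pipeline is testable without external data.

## Worked example

```python
from meripeak.simdata import SimConfig, simulate_reference, simulate_experiment, truth_eval
from meripeak.peakcall import PeakCallConfig, call_peaks

cfg = SimConfig(n_transcripts=10, depth=50_000, seed=42)
ref = simulate_reference(cfg)
paths = simulate_experiment(ref, cfg, "example")          # writes sorted BAMs
peaks = call_peaks(paths["ip"], paths["input"], PeakCallConfig())
retained = [p for p in peaks if p.retained]
print(f"{len(retained)} peaks retained of {len(peaks)} candidate summits")
m = truth_eval(peaks, ref.truth)
print(f"recall {m['recall']:.2f}  precision {m['precision']:.2f}  "
      f"median |summit - site| = {m['median_abs_distance']:.0f} nt")
p = retained[0]
print(f"top peak: {p.chrom}:{p.summit + 1}  enrichment {p.enrichment:.1f}x  q = {p.q_value:.2e}")
```

prints

```
15 peaks retained of 39 candidate summits
recall 1.00  precision 0.93  median |summit - site| = 1 nt
top peak: contig001:1251  enrichment 2.8x  q = 1.11e-179
```

Ten simulated transcripts carry 15 planted sites at eightfold IP
enrichment; the caller finds all of them (one extra summit slips past the
filters, hence precision 0.93) and the summit lands within a nucleotide or
two of the methylated A.  `retained[0].sites` after
`deconv.deconvolute_peaks` would list the deconvolved (site, weight) pairs.

The same pipeline is available from the shell:

```bash
meripeak simulate --out-dir sim --seed 7
meripeak call --ip sim/sim.ip.bam --input sim/sim.input.bam --gtf sim/sim.gtf --out peaks.tsv
meripeak deconvolute --ip sim/sim.ip.bam --input sim/sim.input.bam \
    --fasta sim/sim.fa --gtf sim/sim.gtf --out peaks_sites.tsv
meripeak compare --peaks a peaksA.tsv --peaks b peaksB.tsv --out comparison.tsv
meripeak train-filter --control ctrl.tsv --knockdown kd.tsv --fasta ref.fa --out model.joblib
meripeak score --model model.joblib --peaks peaks.tsv --fasta ref.fa --out scored.tsv
```

Outputs are tab-delimited (1-based coordinates), one file per sample plus a
pairwise comparison table with a log2 enrichment-change column per sample
pair; BED6 export of regions/summits is available for genome browsers.

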