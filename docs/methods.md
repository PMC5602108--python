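# Methods

This note documents the models implemented in `meripeak`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions a maintainer needs.

## Fragment coverage

Coverage is counted per inferred RNA fragment, never per read.  Paired-end
mates are joined into one fragment: each mate's aligned blocks (N CIGAR
operations excluded) are unioned so overlapping mates contribute each base
once, and the inner-mate gap is covered according to context — intersected
with the exon chain of a containing transcript when a GTF is loaded,
filled linearly when narrower than 10 kb, and left uncovered otherwise
(gaps that wide are almost certainly unannotated introns; filling them is
the failure mode that makes DNA-centric peak callers misbehave on spliced
RNA data).  Single-end reads are extended toward their 3′ end to the
configured fragment size (default 100 nt), walking the exon chain when
annotation is available and linearly otherwise; extension past the
transcript end truncates.  For unstranded libraries (`--library-type
unstranded`) the extension is split evenly between both read ends, which
centres the bimodal coverage such protocols produce.  IP and INPUT
libraries receive identical treatment.  Alignment filters (duplicates,
secondary/supplementary, MAPQ, proper-pair) run before fragment inference
and are idempotent.

Library scaling: INPUT coverage is scaled to the IP library by the ratio
of total filtered fragment counts.  Scaling never changes which positions
are zero.

## Peak calling

The IP coverage track is smoothed with a centred moving average (window
defaults to fragment_size/4 rounded up to odd — narrow enough to preserve
sub-peak structure for deconvolution; the window shrinks at track edges).
A summit is a position, or the centre of a run of equal values, whose
preceding flank (expected_width/4, expected_width = 2 × fragment length)
trends upward and whose following flank trends downward.  Summits below
the coverage floor (the minimum-coverage filter value, default 20) are
suppressed before testing, which also prunes the multiple-testing burden.
Adjacent maxima are reported separately only when the valley between them
drops below `min_valley_fraction` (default 0.75) of the lower summit;
shallower dips merge into the higher maximum.  Peak regions span one
fragment length to each side of the summit; overlapping regions are split
at the (ceiling) midpoint between the two summits, so regions are always
disjoint and contain their summit.

Significance: a one-sided Fisher's exact test on the 2×2 table
(region vs rest-of-library fragment counts, IP vs INPUT), computed as the
upper hypergeometric tail.  Fragments are counted in a region when any
block overlaps it — counts must stay integral for an exact test, so no
base-weighting.  The test uses raw counts; smoothing only serves summit
detection.  FDR control: Benjamini–Hochberg by default, with
Benjamini–Yekutieli, Bonferroni and none available.  Enrichment fold is
reported as (ip_count + 1)/(scaled input_count + 1); the pseudocount
avoids infinite folds over empty INPUT.  Filters (q ≤ 0.05, fold ≥ 2,
≥ 20 fragments, optional reproducibility across replicates within a 50-nt
summit window) flag peaks rather than discard them.

## Peak deconvolution

An enriched region's fragment pile-up is modelled as a mixture over
candidate methylated adenosines plus a uniform noise component.  The
placement kernel is deliberately minimal: a fragment of covered length L
whose span contains a site has density 1/L (uniform over the L start
positions that cover the site), zero otherwise; the noise density is
1/region_length.  An empirical fragment-length-weighted kernel can be
plugged in through the same interface.  Because the kernel has hard
zeros, EM uses a floored density (1e-12) for non-covering pairs — the
floor makes the likelihood finite everywhere so the standard monotonicity
guarantee holds, while leaving responsibilities numerically unchanged;
the public `fragment_site_likelihood` still returns exactly 0.

Initialisation is greedy and deterministic: repeatedly choose the
candidate adenosine covering the most not-yet-covered fragments; initial
weights are proportional to the fragments covering each chosen site with
a 0.05 initial noise weight.  The E-step computes responsibilities over
sites and noise; the M-step sets weights to responsibility means and
relocates each site to the candidate maximising its component's expected
log-likelihood (relocation stays on the candidate list — methylation only
occurs at adenosines, so continuous optimisation would be meaningless).
Components collapsing below weight 1e-6 are frozen.  Convergence:
Δlog-likelihood < 1e-4, at most 200 iterations.

Model size is selected by BIC = k·ln(n_fragments) − 2·lnL with
k = 2 × n_sites (each site contributes one position and one free weight;
the noise weight is the simplex remainder).  Models with 1..5 sites are
fitted; ties favour fewer sites.  On simulated single-site regions
(100 fragments of 50 nt, 10% noise) the deconvolved site falls within
±5 nt of the planted A in ≥ 90% of regions and the median error is below
the summit-only median; two sites 80 nt apart at fragment length 50 are
resolved as two components in well over 80% of replicates.

## False-positive filter

Peaks are represented as 200-nt sequences centred on the called site (top
deconvolved site, else the summit), with the site written as the symbol M;
minus-strand transcripts are reverse-complemented first, and windows
running past a contig are N-padded (N positions drop out of likelihoods).

The MTD model approximates an order-L Markov chain as
P(x_t | history) = Σ_l λ_l·Q[x_{t−l}, x_t] with one shared 5×5 transition
matrix Q and lag weights λ on the simplex — parameters grow linearly in L
instead of exponentially (default L = 5; a per-lag-Q variant would
quadruple the parameter count and is not implemented).  Training is EM
over the lag mixture from a deterministic initialisation (uniform λ, Q
from add-one-smoothed lag-1 counts), so fits are reproducible; the
training log-likelihood is non-decreasing.  Separate models are fitted to
TP and FP sequences on a two-thirds split; their log-likelihood ratio
becomes a classifier feature, keeping MTD-fit sequences from leaking into
validation folds.

Labels come from knockdown/control pairs: TP = control peak with no
knockdown summit within 50 nt; FP = matched peak with relative enrichment
change |enr_kd − enr_ctrl|/enr_ctrl < 0.5; everything else is ambiguous
and excluded.

The feature vector (versioned schema, fixed order) covers the MTD
log-likelihood ratio, signed distance to the nearest RRACH A (plus an
absence indicator), enrichment, region fragment count and width,
transcript context (one-hot CDS/5′UTR/3′UTR/exonic/intronic/unknown, exon
length), and k-mer composition for k ≤ 3.  Convention for M in k-mer
counting: M is its own symbol at k = 1 (reported as `m_count`; the A
count excludes it) and maps back to A for k = 2, 3 so context k-mers stay
on the ACGT alphabet.  Conservation and miRNA-site columns join as
optional extras; predicted RNA secondary structure is excluded by design.
The ensemble is a random forest (1000 trees, 6 features per split,
out-of-bag error reported); the peak score is the fraction of trees
voting TP — 0–0.5 suggests a false positive, 0.5–1.0 a genuine site — and
the threshold is the precision/recall bias knob.

## Synthetic data

The generator emulates the m⁶A-seq design: 50 single-strand transcripts
of 1.5–3 kb with 1–3 exons on one contig each, expression drawn
log-normally (σ = 0.5), one or two sites per transcript planted at
RRACH-context adenosines (≥ 150 nt from transcript ends, ≥ 250 nt apart),
100 ± 20 nt fragments sequenced as 50-nt paired-end reads, 2×10⁵
fragments per library and 10% non-specific IP background.  INPUT
fragments are uniform along transcripts in proportion to expression; IP
fragments mix background with site-covering placements whose mixture
weight is chosen so the expected IP/INPUT coverage ratio at a site equals
the configured eightfold enrichment.  Signal placement uses the same
admissible-placement kernel the deconvolution model assumes, which makes
parameter-recovery tests exact; a `--no-motif` mode plants sites at
arbitrary adenosines to probe the consensus-restricted mode's failure
behaviour, and `noise_fraction = 1` produces a null experiment for
type-I-error checks.

Not emulated: sequencing errors and base qualities, PCR duplicates (the
filters are tested on hand-flagged records), GC/coverage bias,
overlapping genes, antisense transcription and expression-level
heteroscedasticity beyond the log-normal.  Passing tests therefore show
algorithmic correctness under the stated generative model, not robustness
to every artefact of real libraries — in particular the placement kernel
matches the simulator by construction, so real-data resolution will be
somewhat worse than the synthetic numbers.

## Problem sizes and numerics

The test suite and the acceptance script keep simulations at desk scale:
the standard end-to-end fixture uses 50 transcripts and 2×10⁵ fragments
per library; null calibration uses four 10⁵-fragment replicates (~2100
regions); deconvolution statistics use 200 single-site and 60 two-site
regions; MTD recovery uses 10⁵ transitions; the classifier benchmark uses
2000 points in 10 dimensions with 100-tree forests inside 10-fold CV.
These sizes give stable statistics while a full run stays in the minutes
range on one CPU.

Conventions: 0-based half-open coordinates internally, 1-based inclusive
in all text output; exact-test p-values via the hypergeometric survival
function; even smoothing windows are incremented; plateau summits report
the run centre; cross-sample matching is greedy nearest-summit with a
position-sorted pool and per-sample uniqueness, making it independent of
sample order; floats are written at 6 significant digits and round-trip
at that precision.
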