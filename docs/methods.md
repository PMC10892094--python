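# Methods

`m6adyn` re-implements, as a tested pipeline with a synthetic ground-truth
generator, the analysis chain used to study m6A epitranscriptome dynamics
under copper-induced oxidative stress in Arabidopsis: m6A-IP-seq peak
calling against an input library, three-replicate consensus, condition
classification of peaks and transcripts, positional profiles, abundance and
polysome-occupancy statistics by m6A category, and k-mer motif enrichment.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Coordinate model

All intervals are 0-based half-open on a stranded genome (BED convention);
GTF 1-based inclusive coordinates are converted at the I/O boundary.
Transcripts carry their spliced exon structure; genome-to-transcript
mapping is defined only for exonic bases and orients positions 5'→3' on the
transcript (minus-strand transcripts count from the genomically rightmost
base). The CDS includes the stop codon; the stop-codon anchor used by the
frequency profile is the first base of the stop codon (CDS end − 3 in
transcript coordinates). When a gene has several isoforms, transcript-level
analyses use the longest isoform (ties broken by identifier) — a
deterministic rule chosen because collapsing conventions differ between
tools and none is canonical.

## Synthetic data generator

The generator emulates the study design end to end so that every
downstream stage can be scored against known truth:

* **Transcriptome.** 2000 transcripts (default) tiled over 4 chromosomes
  with 200–500 nt intergenic gaps; 1–3 exons each (introns 60–200 nt,
  every exon long enough to host a peak). Coding transcripts draw
  5'UTR/CDS/3'UTR lengths from gamma distributions with means 150/900/250
  nt (floors 60/300/120); ~10% of transcripts are non-coding with biotype
  shares lncRNA 0.50, ncRNA 0.25, miRNA precursor 0.15, snoRNA 0.10, so
  lncRNA is the largest methylated ncRNA class, with plain ncRNA second.
  Genome sequence is uniform random ACGT.
* **Planted methylation.** 60% of transcripts carry exactly one m6A peak of
  150–200 nt, constrained to a single exon. Peak classes follow the
  observed proportions: 15% stress-only, 18% control-only, the rest shared.
  Placement follows a per-class probability vector over {5'UTR, start ± 50
  nt, CDS, stop ± 50 nt, 3'UTR}: shared peaks are strongly 3'UTR-biased
  (0.05/0.05/0.15/0.10/0.65 — plant m6A sits within the 3'UTR rather than
  centred on the stop codon, which is the mammalian signature), while
  condition-specific peaks shift toward the 5'UTR/start
  (0.20/0.20/0.25/0.10/0.25). Peaks aimed at a pure region (5'UTR, CDS,
  3'UTR) are kept inside that region whenever it is at least one peak
  length long, so a "3'UTR peak" does not bleed across the stop codon.
  The ±50 nt codon-proximal window is narrower than the ±100 nt plotting
  window so planted signal stays inside the plotted range.
* **Motif.** The RNA motif UGUA is planted as DNA "TGTA" on the sense
  strand (reverse-complemented into the reference for minus-strand
  transcripts) at rate 0.8 per peak at a random offset, and at a low
  background rate (0.05 per ~175 nt of transcript) elsewhere.
* **Windowed IP/input tracks.** Counts are simulated per fixed 25-nt window
  rather than per read: the Poisson-enrichment statistics the caller tests
  survive windowing, while alignment stays out of scope. Input coverage is
  depth 30 reads/window (the `depth` parameter is the mean *input reads per
  window*) modulated by mild region multipliers (5'UTR 0.6×... see below)
  emulating the CDS bias of real RNA-seq: 0.85/1.25/0.85 for
  5'UTR/CDS/3'UTR. IP means equal input means except inside a peak active
  in that condition, where they are multiplied by `ip_enrichment` (8×).
  Counts are negative binomial with inverse-size `window_dispersion` =
  0.005: within one library, windowed read counts are close to multinomial
  sampling, so only a small residual overdispersion is realistic — and this
  value makes the caller's null false-window rate sit at α (Monte-Carlo
  over 10^6 windows: 0.0506 at α = 0.05). Each sample gets a library-scale
  factor drawn uniformly from [0.85, 1.15].
* **Expression and polysome counts.** Per-transcript baselines are
  lognormal (mean 200 counts, σ = 0.8). RNA-seq has 3 replicates per
  condition, polysome-seq 2, both negative binomial with biological
  dispersion 0.05. Hosts of stress-only peaks get +0.5 log2 abundance under
  copper (−0.5 for lncRNA hosts, which buck the mRNA trend) and +0.5 log2
  polysome occupancy; hosts of control-only peaks get −0.5 log2 abundance.
  Effect sizes are free parameters chosen for detectability at the
  simulated depth, not literature values.

Every stage owns an independent random stream spawned from the single
config seed, so each generator function is individually deterministic and
the whole simulation is byte-reproducible.

## Peak calling

The caller is a strand-split windowed Poisson test of IP against
depth-scaled input — the statistical core of MACS2's narrow-peak mode,
re-implemented openly because the full MACS2 machinery (fragment model,
duplicate filtering, λ-tiers, q-values) is out of scope. Per window,

λ(w) = max( smoothed_input(w) × L_IP/L_input , λ_floor ),
p(w) = P( Poisson(λ(w)) ≥ k_IP(w) ),

where `smoothed_input` is a centred 41-window (~1 kb) moving average — the
scale of MACS2's local background — and λ_floor is the mean input count
over *covered* (nonzero) windows scaled by the library ratio. A raw
per-window λ from a single noisy input track is badly anti-conservative
(analytic false-window rate ≈ 0.12 at depth 30); smoothing restores
calibration, and the covered-window floor prevents both p = 0 artifacts on
isolated zero-input windows and systematic λ underestimation at transcript
edges, where a symmetric smoother averages in intergenic zeros. Setting
`smooth_windows=1` recovers the raw per-window λ.

Windows with p < 0.05 (the unadjusted threshold used in the original
analysis; no multiple-testing correction at this stage) are merged across
gaps of at most one window; merged runs with fewer than `min_windows = 6`
significant windows (150 nt) are dropped — the same role the
fragment-length minimum peak size plays in MACS2, and necessary because at
a 5% per-window rate a two-window minimum would emit hundreds of false
merged peaks over ~10^5 background windows. Each peak reports its summit
(midpoint of the maximum-count window), an enrichment score
(Σk_IP / Σλ over the span) and the minimum window p-value. Note the score
is conservative when the IP library is globally enriched, because the
library-size ratio scales λ up. Called peak boundaries are quantised to
the 25-nt window grid, so called lengths exceed planted lengths by up to
one window per side; recovery checks therefore allow [150, 250] nt for
planted 150–200 nt peaks.

## Consensus and classification

A high-confidence peak needs one member from **every** replicate of its
condition, all mutually overlapping (≥ 1 nt, same strand; a minimum overlap
fraction is config-exposed). Candidate groups are formed greedily in
coordinate order and each member joins at most one consensus; the consensus
interval is the union (hull) of its members — the union-vs-intersection
choice is not documented in the original analysis, and union is the
declared choice here. Comparing the two conditions' consensus sets,
a stress peak overlapping any control peak (≥ 1 nt, same strand) is
*shared* — reported once, with stress-side coordinates to avoid double
counting — otherwise *stress-enriched*; control peaks symmetric. Peaks are
assigned to every transcript whose exons they overlap on the same strand;
transcript labels follow the precedence stress > control > shared (the
original analysis does not address transcripts hosting several categories),
and peaks overlapping no transcript are retained in an intergenic bucket.

## Positional profiles

* **Metagene.** Each region (5'UTR, CDS, 3'UTR) of each coding transcript
  is split into a fixed *count* of bins (20/region by default) with
  fractional-nt edge weighting; "100-nt bins" is ambiguous between width
  and count, and variable-length UTRs cannot share a fixed-width axis.
  Per-bin per-nt densities are normalized by the transcript's total and
  averaged, making the profile invariant to transcript order and to global
  library scaling. Profiles are computed over the transcripts *detected* as
  methylated (hosts of consensus peaks) — the population an IP library
  represents; over all transcripts the unmethylated majority, whose IP
  coverage is just CDS-biased background, dilutes the 3'UTR signal.
  The input profile over the same transcripts shows the CDS maximum that
  background RNA-seq coverage produces.
* **Per-nucleotide frequency.** For transcript positions within ±100 nt of
  the start/stop codon, raw frequency = (# unique category peaks
  overlapping that position) / (# methylated transcripts in the category),
  then max-normalized over the window. The denominator population is read
  category-wise (coding transcripts of that category); the alternative
  reading (all methylated transcripts) only rescales curves within a
  category and cannot change the cross-category ordering of normalized
  profiles. Empty categories yield flagged all-zero profiles.
* **Feature breakdown.** Each peak votes once, by the feature its summit
  falls in on its longest host transcript (full-span multi-voting is
  available via flag); start/stop features are the 3-nt codons themselves,
  widenable via `codon_flank`. Percentages per category sum to 100.

## Quantification

The differential-abundance stage is an explicitly simplified stand-in for
a negative-binomial Wald pipeline: median-of-ratios size factors (rescaled
to geometric mean 1), log2 fold change of normalized condition means with
pseudocount 1, Welch t-tests on log2-normalized counts, and
Benjamini–Hochberg adjustment (Bonferroni available; the original methods
text names Bonferroni for a package whose default is BH). The category
conclusions rest on the rank-sum comparisons, which are implemented
exactly. With 3-vs-3 replicates the Welch test is underpowered relative to
a shrinkage-based NB model, so transcript-level significant calls are few;
this is a known limitation, not a target of the category-level statistics.

Polysome occupancy per condition is log2(polysome RPM / RNA RPM) with RPM
averaged over replicates within assay × condition; occupancy change is the
copper-minus-control difference, exactly. Transcripts with any of the four
mean RPM cells below 1.0 are excluded to keep logs finite. Because RPM
normalization fixes only the per-library total, planting shifts in a large
fraction of the transcriptome moves condition totals and adds one global
constant to every transcript's occupancy change; planted occupancy effects
are therefore recovered (and tested) as the contrast against the unshifted
shared category — the same contrast the category comparison measures.

Category comparisons are two-sided Mann–Whitney rank-sum tests (Welch
t-tests for the ncRNA groups, following the methods text; both exposed).
Two identical samples return p = 1 by convention. ">50% increase/decrease"
threshold counts are normalized copper/control ratios > 1.5 or < 0.5.

## Motif enrichment

Peak sequences are spliced, transcript-orientation extracts (junction
peaks yield junction sequences; minus-strand peaks are
reverse-complemented). The de novo motif stage is replaced by a k-mer
test exercising the same enrichment question: for every k-mer (k = 4–6),
the foreground occurrence count is tested with a binomial upper tail
against the rate in a background of 100 Altschul–Erickson
dinucleotide-preserving shuffles per sequence (exact mono- and
dinucleotide composition, so enrichment reflects order beyond
composition); BH-adjusted p-values, ranked by p, then enrichment fold,
then lexicographic k-mer — fully deterministic under a fixed seed. The
background rate is floored at half a count to avoid zero rates.

## Numerical and degenerate-input conventions

Poisson/NB/binomial tails come from scipy and are verified against direct
summation oracles to 1e-12. Empty peak lists, all-zero IP tracks, empty
categories and transcripts missing a region are defined no-ops or logged
exclusions rather than errors; all-zero *input* tracks are errors (no
background rate exists). NarrowPeak −log10 p-values are written at full
float precision so files round-trip; p = 0 is encoded as 9999.

## Problem sizes and what the tests show

The test suite and the acceptance script run the generator at 2000
transcripts (the default study condition), 1700 transcripts with raised
class fractions for the ≥ 500-per-category effect-recovery checks, and
200–300 transcripts for end-to-end determinism demos. The generator
emulates windowed count statistics, positional structure, and
condition-linked effect sizes; it does not model read-level artifacts
(sequencing error, PCR duplicates, fragmentation bias, mappability),
isoform complexity, or correlated biological variation between transcripts.
Passing recovery tests therefore validate the implementation of the
statistics and set algebra under the stated count models — not robustness
to those unmodelled features of real libraries.
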