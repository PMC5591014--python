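# Methods

## Contact model and assumptions

4C-seq measures, for one viewpoint fragment, how often every other
restriction fragment in the genome is ligated to it. The analysis assumes
(i) that the background contact frequency decreases monotonically with
genomic distance from the viewpoint (polymer behavior of the chromatin
fiber), without committing to any parametric form; and (ii) that specific
chromatin contacts appear as localized departures *above* that background.
The pipeline therefore fits a shape-constrained (non-increasing isotonic)
regression of windowed capture frequency on distance rank and scores the
residuals, rather than fitting a power law or exponential. Fitting on
distance *rank* makes the fit invariant to any monotone transform of
distance; fitting each side of the viewpoint separately allows asymmetric
chromatin context (a `symmetric=True` option pools sides by absolute
distance).

Capture calling is deliberately strict: a fragment end is captured only by
a read that starts exactly at the end and points into the fragment. This is
what distinguishes genuine ligation junctions from background coverage, and
it is what makes the caller immune to the noise reads the generator plants
at non-end positions.

The residual scale is σ̂ = 1.4826 × MAD (floored at 1e−6) rather than a
standard deviation, so that the true contacts being sought do not inflate
the noise estimate they are tested against. p-values are one-sided
(enrichment only): the analysis looks for contacts, not depletions. The BH
family is all non-excluded windows of the analyzed region within one
replicate. The consensus rule — z > 2 in every replicate and BH q < 0.05 in
at least one — trades a weak per-replicate threshold for replication: two
independent z > 2 events are already rare under the null, and the q
condition anchors the call to the tail of at least one replicate's
distribution.

### Units of analysis

Windows are sliding (step 1 fragment) spans of W = 30 consecutive
fragments; a window holds at most 2W = 60 captured sites, and frequency is
f = c/(2W) ∈ [0, 1]. Sliding rather than tumbling windows preserve
resolution; because the monotone fit is rank-based, results are invariant
to the 1/(2W) rescaling. One consequence to keep in mind when reading
output: a single enriched run of fragments legitimately lights up all ~W
windows that touch it, so consensus calls come in runs of adjacent windows,
not as single hits. Windows within ±2 fragments of the viewpoint are masked
(self-ligation and undigested artifacts dominate there); the radius is
configurable.

## Differential comparison

Samples are made comparable by scaling each to the across-sample mean of
total captured-end weight in a 15 Mb region centered on the viewpoint
(configurable `normalization_span_bp`); this assumes the bulk of regional
signal is condition-independent. The per-window test is an exact
conditional binomial: given the window's total raw count across two
conditions and effective library sizes, the condition-A sum is binomial
under the null, and the two-sided p sums all outcomes no more probable than
the observed one. The test is computed at dispersion 0; a method-of-moments
common-dispersion estimate across windows is reported as a diagnostic, and
when it is materially positive the p-values should be read as
anti-conservative — a documented limitation accepted in exchange for a
fully self-contained exact test.

## Proximity analyses

Distance from a TSS to an interval is measured to the interval's nearest
occupied base (`start … end−1`), 0 when the TSS lies inside; window
frequencies use TSS-centered windows [TSS − w/2, TSS + w/2). Relative
frequency divides by the unchanged-expressed class, the natural reference
population of expressed genes whose regulation did not respond. The
permutation null draws N = 5,000 equally sized gene groups without
replacement from all expressed genes and uses the add-one estimator
p = (1 + #{null ≥ obs})/(N + 1), so the smallest attainable p is 1/5001;
the statistic is pluggable (mean nearest distance by default) because the
same null applies to several summaries. Mann–Whitney comparisons use
midrank ties, exact enumeration when n + m ≤ 14 with no ties, and the
tie- and continuity-corrected normal approximation otherwise. Meta-profiles
z-score extracted values per chromosome (removing chromosome-level baseline
differences in ChIP signal) and smooth class averages with a centered
moving average (5 bins of 10 bp by default); minus-strand genes are flipped
so downstream is positive.

## Virtual digestion conventions

Fragment boundaries sit at the first base of each first-cutter site (blunt
model). Real DpnII cleavage leaves a 5′ overhang, but fragment *identity*,
not ligation chemistry, is what the analysis consumes; the convention only
needs to be fixed and stated. Consequences: a cut at position 0 creates no
empty leading fragment, and under reverse complementation interior
fragments mirror exactly while the two terminal fragments shift by the
motif length. Motif matching steps by one base (overlapping occurrences
allowed, duplicate boundaries deduplicated), never matches across an `N`,
and scans both strands when a non-palindromic motif is supplied. Blind
fragments (no second-cutter site) are annotated but not treated specially
beyond that; modeling their anomalous library behavior is out of scope.

## Synthetic data: what it emulates and what it does not

The generator produces the *structure* of the real inputs with known
truth, all reproducible from one seed fanned out into named substreams
(genome, reads, genes, track):

- **Genome**: i.i.d. background sequence scrubbed of accidental cutter
  motifs, then `GATC`/`GTAC` sites injected as a Poisson process
  (default rate 1/250 bp ≈ the DpnII site density of mammalian genomes,
  default length 500 kb ≈ one analyzed locus). Scrubbing makes the realized
  digest equal the planted site list exactly, which the digestion tests
  rely on.
- **4C reads**: each fragment end is captured independently with
  probability P(d) = min(0.9·(max(d, d₀)/d₀)^(−α), 0.95), α = 1,
  d₀ = 20 kb. The plateau reflects the near-saturation of 4C capture for
  tens of kb around the viewpoint; fold-enrichments are planted
  multiplicatively at distances where the fold is realized below the cap
  (a fold planted inside the saturation zone would be silently truncated).
  Captured ends emit 1 + NB reads (mean 3, dispersion 0.5) at the exact end
  position in the inward orientation; 10% of reads are noise at non-end
  positions and must be ignored by capture calling. Default planted
  contact: 10-fold over 10 fragments ~200 kb downstream.
- **Gene fixture**: four classes × 200 genes on four 50 Mb chromosomes;
  TSS-to-feature distances are exponential with scale 20 kb, divided by the
  class effect (down-class enhancer effect 4, CTCF effect 2 for up and
  down) — exponentials give closed-form expectations for analytic checks.
  The signal track is Gaussian bumps (height 5, SD 300 bp) at CTCF peak
  centers on per-chromosome baseline offsets.

Not emulated: sequencing errors, PCR duplicates, mappability, blind-end
library artifacts, undigested/self-ligation products (masked rather than
modeled), correlated capture between neighboring fragments, TADs or other
higher-order structure, and real gene/peak density heterogeneity. Passing
tests therefore demonstrate that the statistical machinery recovers planted
effects under its own model assumptions — not that those assumptions hold
for any particular real library.

## Numerical choices

- Isotonic fit via pool-adjacent-violators (scikit-learn backend); within
  each level set the residual mean is 0 to ~1e−12, which the tests assert
  against a brute-force level-set enumeration.
- Normal tail p-values are clipped to ≥ 1e−300 before BH (the survival
  function underflows for extreme z).
- The exact binomial test compares outcome probabilities with a 1 + 1e−9
  relative tolerance when collecting the "no more probable" set, and clips
  the summed p at 1.
- The decay-exponent diagnostic (`estimate_decay_exponent`) averages window
  frequencies within log-spaced distance bins *before* taking logs
  (avoiding the bias of log-transforming near-zero counts), then fits a
  weighted least-squares slope; windows inside the saturation plateau must
  be excluded via `min_distance`.
- All-zero capture on one side of the viewpoint yields a zero fit with z = 0
  and a warning rather than an error; fewer than 5 usable windows per side
  is an error.
- Degenerate inputs are contracts, not surprises: empty chromosomes,
  inverted intervals, non-integer counts in the exact test, a missing seed
  for any stochastic operation, and unknown config keys all raise with the
  offending item named.

## Problem sizes

The shipped simulations use 2,000 fragments per locus (≈500 kb at DpnII
density), two replicates per condition, 50 seeds for recovery summaries,
50–200 seeds for null calibration, and the full N = 5,000 permutation
draws. These sizes give Monte-Carlo error comfortably below the effects
being measured while keeping a full run of the suite and the acceptance
script in the low minutes on one core.

## Known limitations

- The dispersion-0 exact test understates variability for overdispersed
  libraries; the reported moment dispersion flags this but does not correct
  it.
- The isotonic background partially absorbs very wide enrichments (a bump
  spanning many windows is monotone-compatible on its shoulders), biasing z
  downward for broad domains; the method targets localized contacts.
- Consensus calling requires identical window grids across replicates —
  replicates must be processed against the same fragment map.
- Meta-profile z-scoring uses only the extracted ±2 kb values per
  chromosome, not genome-wide moments; with few genes per chromosome the
  standardization itself is noisy.
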