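# Methods

## Coordinate model

All intervals are 0-based half-open (BED convention), including distance
arithmetic: the gap between `[a,b)` and `[c,d)` is `max(0, max(a,c) −
min(b,d))`, so overlapping or book-ended intervals are at distance 0.
Unknown chromosomes in BED input are a hard error rather than silently
dropped, so genome/annotation mismatches surface immediately. Strand is
ignored everywhere except metagene orientation.

## Overlap counting semantics

`count_overlaps` counts (query, subject) **pairs** sharing ≥ 1 bp — the
default semantics of `bedtools intersect`, under which one peak hitting
three feature copies contributes three. "Total number of overlaps" in the
enrichment statistic is read this way. The alternative reading
(queries-with-any-hit) is partially captured by `count_overlaps_dedup`,
which collapses multi-copy features to at most one count per distinct
subject name; it exists because tRNA genes occur in many identical-sequence
copies and are conventionally counted once per unique gene sequence. Both
counters are checked against brute-force all-pairs oracles.

## Permutation enrichment

The null preserves each peak's chromosome and width and redraws its start
uniformly on `[0, L_chrom − w]`; shuffled peaks may overlap one another
(no exclusion masking, matching the plain `-chrom` shuffle). One stream of
`n_perm` shuffled peak sets is drawn per call and **every** feature label is
counted against the same stream, so per-feature results are positively
correlated exactly as when shuffled peak files are intersected with each
annotation in turn. Empirical p-values are two-sided by doubling the smaller
tail with a +1 add-one correction, `p = (1 + 2·min(g, l)) / (n_perm + 1)`
capped at 1, so p is never 0 and the resolution floor is `1/(n_perm+1)`;
the doubling convention is the standard conservative choice where the
two one-sided proportions could also have been summed or capped.
Benjamini–Hochberg correction is applied across the labels of one call
(statsmodels' step-up implementation). With defaults the shuffle stream is
consumed chromosome-by-chromosome in genome order within each replicate
block, making runs bit-reproducible for a given seed.

Calibration: on length-proportionally placed null peaks the p-value is
slightly conservative by construction (add-one correction plus discrete
counts); measured type-I error at α = 0.05 is ≈ 0.04–0.06 per chromatin
state at 1000 peaks and 500 permutations.

## Binomial density tests

Peak counts are normalised per Mb of arm length. The X-vs-autosome test is
an exact binomial of the X count among all peaks at `p₀ = L_X / L_total`,
two-sided by the minimum-likelihood convention (sum of all outcome
probabilities ≤ the observed outcome's), matching R's `binom.test`. The
same construction gives the motif-density test with motif occurrences in
place of peaks.

## Rank-sum comparisons

`rank_sum_test` returns the Mann–Whitney U of the first sample with midrank
ties. For `n_a + n_b ≤ 12` without ties the two-sided p comes from exact
enumeration of all rank assignments (double the smaller tail, capped at 1);
otherwise the normal approximation with tie and continuity corrections is
used (scipy's asymptotic method). Identical pooled values give p = 1 by
convention. The asymptotic branch deviates from the exact enumeration by
< 0.02 at n = 6 + 6.

## Metagene profiles

Scale-regions geometry: 1000 bp flanks and a 3000 bp nominal body at 50 bp
bins (20 + 60 + 20 bins). Flank bins are fixed genomic windows; body bin
edges are fractional (`start + k·len/60`) and averaged with exact length
weighting against the piecewise-constant track, which matches a per-bp
oracle to 1e-9. Minus-strand rows are reversed so bin 0 is always 5'-most.
Flank windows extending past a chromosome end contribute zero signal but
full window length. All-zero rows are dropped by default (`skip_zeros`),
and a group of one region gets SEM 0 with a warning. The gene "body" spans
annotated TSS→TES including UTRs; isoform choice is left to the caller,
which passes one region per gene.

## Depth titration and the stand-in peak caller

Depth manipulation operates on binned integer counts: each bin count k is
replaced by Binomial(k, fraction), the binned equivalent of retaining reads
independently. The caller is a sliding 4-bin-window Poisson test of IP
counts against the library-size-scaled control window, floored at the
genome-wide mean IP count per window, with significant windows (upper-tail
p < 1e-3) merged when adjacent or book-ended. It is intentionally minimal —
no local-lambda, duplicate handling, or fragment model — and exists so that
depth effects on peak yield are exercisable end to end. The genome-wide
floor is what produces the depth artifact: an arm sequenced at half depth
sits far below the genome-wide background, so its true sites fail the
threshold until the other arms are thinned to match.

## Synthetic data

The generator emulates the data structure of a sexed DRIP-seq experiment,
not its sequences. One
`numpy` generator seeded from `SyntheticConfig.seed` drives all stages in a
fixed order (states, genes, tRNAs, peaks, DE labels, per-sample sets,
sequence + motifs, CES, expression, tracks), so datasets are deterministic
per seed.

- **Genome**: the five major *D. melanogaster* arms at 1:100 scale
  (≈ 235–321 kb each; ~1.33 Mb total) so full 10,000-iteration permutation
  runs finish in seconds; `REAL_CHROM_LENGTHS` restores full scale.
- **Chromatin states**: an exact exponential-length tiling (mean 3 kb, min
  300 bp) with labels drawn at RED .10 / YELLOW .15 / BLUE .10 / GREEN .15 /
  BLACK .50 — the gene-poor BLACK state is the largest, as in the
  five-colour classification.
- **Peaks**: chromosome chosen ∝ length × X-multiplier (default 2.0, the
  reported ≈ 2-fold X density excess), then start rejection-sampled within
  the chromosome ∝ the state multiplier at the peak midpoint (defaults
  RED 3.0, YELLOW/BLUE 1.5, GREEN 0.4, BLACK 0.3, mirroring the observed
  enrichment pattern). Rejection within the chromosome keeps per-arm counts
  exactly multinomial, so the X:A ratio is independent of state noise.
  Widths 3–15 bp (≈ 300–1500 bp at scale). Peaks may overlap each other;
  no statistic uses disjointness.
- **DE labels**: drawn directly at the published class fractions
  (558/15281 FE, 1282/15281 ME); ME peaks are picked from X-linked peaks
  with probability 0.45. Per-sample peak sets subsample the consensus with
  sex-appropriate inclusion rates (0.95 shared, 0.9 own-sex, 0.15
  cross-sex). No differential-binding model is simulated — the labels are
  pipeline inputs, as in the upstream differential-binding workflow.
- **Tracks**: half-normal background noise plus, for peak-bearing genes, a
  Gaussian bump just downstream of the TSS on autosomes and a broad
  gene-body elevation with a 3' shoulder on the X, amplitudes scaled by
  expression — the qualitative autosome-vs-X metagene contrast.
- **Sequence and motifs**: uniform A/C/G/T background with motif instances
  (degenerate positions resolved at random, strand random) planted without
  mutual overlap at 1.4-fold X density, so scanning has exact ground truth:
  background collisions can add hits but never remove planted ones.
- **Expression**: N(5, 1) baseline, +1 SD for peak-bearing genes, ±0.8 for
  FE/ME genes by sex, per-sample N(0, 0.3) noise; presence calls are
  Bernoulli with a logistic link on mean expression.
- **Depth experiment** (`generate_depth_tracks`): Poisson counts at 10 per
  50 bp bin, 4-bin enrichment sites at amplitudes U(1.55, 2.2)×background —
  chosen to straddle the caller's detection thresholds (1.55×λ at full
  depth, 1.80×λ at half depth), so detection is depth-sensitive — with
  2-fold X site density and X coverage at half depth.

What the generator does **not** model: read-level data (FASTQ, fragment
sizes, GC bias), replicate structure / IDR, mappability, isoforms, real
motif position-weight matrices, or genome sequence composition. Passing
tests therefore demonstrate correctness of the statistics and their
calibration under the stated generative model, not robustness to artifacts
of real libraries.

## Design choices where the design was open

- **Gene-label precedence** FE > ME > nonDE for genes overlapping several
  peak classes (exposed as an argument): the rarer sex-biased classes would
  otherwise be swallowed by the abundant shared class.
- **Motif scanning** is exact IUPAC-consensus matching, not PWM log-odds
  scoring — adequate for the per-Mb density ratio; overlapping occurrences
  are all counted, and a position matching on both strands (palindromes)
  counts once.
- **Distance to entry sites** is log2(bp + 1) so overlapping peaks
  (distance 0) are admissible on the log scale.
- **Two-sided empirical p** doubles the smaller tail (see above).
- **Downsampling on bins, not reads**: the artifact has no read-level data
  model, and binomial bin thinning has the same first two moments as read
  subsampling of the binned counts.

## Numerical notes and limitations

- Overlap counting is O((n+m) log m) per chromosome via sorted
  boundary-rank differences; permutation replicates are vectorised in
  blocks, and the dedup (unique-name) counter materialises a
  replicate × peak × subject tensor per chromosome, which is fine at study
  scale but would need chunking for feature sets with many thousands of
  named intervals.
- `log2(obs/exp)` is NaN when either side is 0 (empty feature sets yield
  observed 0, expected 0, p 1).
- The binomial density test treats peaks as independent trials; wide peaks
  spanning arm boundaries do not exist by construction, but peak clustering
  (which the generator produces inside enriched states) mildly inflates its
  significance relative to a cluster-aware null. The permutation test does
  not have this issue.
- Acceptance-scale simulation sizes (200 null replicates × 500
  permutations; 20 depth-experiment seeds; 10,000 uniformity draws) were
  chosen to keep the whole suite under a minute of compute while leaving
  the binomial noise on each checked rate well inside its assertion band.
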