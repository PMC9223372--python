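# rloopkit

Statistical analyses for R-loop (DRIP-seq) peak landscapes, built around the
question of where R-loops form in a genome and how their distribution differs
between sexes.

R-loops are three-stranded structures — a DNA:RNA hybrid plus a displaced
single strand — that form co-transcriptionally and mark loci under torsional
stress. DRIP-seq (DNA:RNA immunoprecipitation with the S9.6 antibody) yields
peak sets per sample; the scientific questions this package answers about
such peak sets are:

- **Feature / chromatin-state enrichment.** For a peak set *P* and feature
  set *F*, the observed statistic is the number of overlapping pairs
  `obs = #{(p, f) : p ∩ f ≠ ∅}`. The null is a chromosome- and
  width-preserving shuffle (every peak keeps its arm and width, start
  uniform where it fits; the analogue of `bedtools shuffle -chrom`).
  Enrichment is reported as `log2(obs / mean(obs*))` over 10,000 shuffled
  replicates, with a two-sided empirical p-value
  `p = (1 + 2·min(#{obs* ≥ obs}, #{obs* ≤ obs})) / (n_perm + 1)` and
  Benjamini–Hochberg correction across features. Multi-copy features
  (e.g. tRNA genes) can be counted once per distinct name.
- **Chromosome density.** Peaks per Mb by arm, with an exact two-sided
  binomial test of the X count against the null `p₀ = L_X / L_genome`
  (minimum-likelihood two-sided convention, as in R's `binom.test`).
- **Metagene profiles.** Scale-regions binning (1 kb flanks, 3 kb scaled
  body, 50 bp bins → 20 + 60 + 20 bins), strand-oriented, with exact
  length-weighted averaging and per-bin mean ± SEM by group.
- **Sequencing-depth titration.** Binomial thinning of binned coverage plus
  a deliberately simple sliding-window Poisson peak caller, to demonstrate
  how peak yield scales with depth and how unequal per-arm depth creates a
  spurious X-chromosome peak depletion that reverses after depth matching.
- **Sex-bias summaries.** Peaks labelled nonDE / FE / ME (shared,
  female-enriched, male-enriched) are summarised (% sex-biased, ME:FE
  ratio), profiled per chromosome, and propagated to genes
  (FE > ME > nonDE precedence, else `no_R_loop`); per-gene quantities
  (expression, log2 distance to dosage-compensation entry sites, MOF /
  H4K16ac signal) are compared across groups with Mann–Whitney rank-sum
  tests (exact enumeration for small tie-free samples).
- **Motif density.** IUPAC consensus scanning on both strands with
  overlapping matches, and `log2((hits_X/Mb_X) / (hits_A/Mb_A))` with a
  binomial test.

Everything runs against a seeded synthetic-data generator
(`rloopkit.simulate`) that emulates the study design on a five-arm genome
(2L, 2R, 3L, 3R, X at 1:100 scale): a five-colour chromatin-state partition,
gene models with UTR/CDS/intron structure, ~2-fold X-enriched peak density,
nonDE/FE/ME labels with ~12 % sex-biased peaks, TSS-proximal autosomal vs
gene-body-broad X signal, planted motif occurrences, and expression higher at
peak-bearing genes — so every analysis is testable without any download.

## Worked example

```python
import rloopkit as rk

ds = rk.generate(rk.SyntheticConfig(seed=1, n_peaks=3000))

res = rk.chromosome_density_test(ds.consensus_peaks, ds.genome)
for c, d in res.per_chrom_density.items():
    print(f"{c:3s} {d:8.1f} peaks/Mb")
print(f"X count {res.x_count}/{res.total}, null p0={res.p0:.3f}, "
      f"binomial p={res.p_binom:.3g}")

results = rk.permutation_enrichment(
    ds.consensus_peaks, ds.state_features(), ds.genome, n_perm=1000, seed=1
)
print(rk.enrichment_frame(results).to_string(index=False))

s = rk.summarize_de_counts(13441, 558, 1282)
print(f"sex-biased: {s.pct_sex_biased:.1f}%  ME:FE = {s.me_fe_ratio:.2f}")
```

prints

```
2L    1943.5 peaks/Mb
2R    1846.8 peaks/Mb
3L    1896.1 peaks/Mb
3R    1979.5 peaks/Mb
X     3856.9 peaks/Mb
X count 908/3000, null p0=0.178, binomial p=2.04e-62
feature  observed  expected  log2_ratio        p        q  n_perm
    RED      1137   392.299    1.535207 0.000999 0.000999    1000
 YELLOW       656   418.163    0.649630 0.000999 0.000999    1000
   BLUE       539   347.435    0.633542 0.000999 0.000999    1000
  GREEN       237   550.234   -1.215158 0.000999 0.000999    1000
  BLACK       436  1299.264   -1.575295 0.000999 0.000999    1000
sex-biased: 12.0%  ME:FE = 2.30
```

The X arm carries roughly twice the autosomal peak density (the planted
2-fold X enrichment; binomial p rejects the length-proportional null), the
active RED state is ~3-fold enriched (log2 ≈ 1.5 against the shuffle
expectation) while the repressive GREEN/BLACK states are depleted, and the
published differential-enrichment class sizes give ~12 % sex-biased peaks
with a 2.3-fold male excess.

A command-line interface wraps the same stages:

```sh
rloopkit demo --seed 7 --out out/          # end-to-end on synthetic data
rloopkit enrich --peaks peaks.bed --features-dir features/ \
    --genome genome.chrom.sizes --n-perm 10000 --seed 1 --dedup tRNA --out out/
```

Subcommands: `simulate`, `enrich`, `density`, `metagene`, `downsample`,
`motifs`, `sexbias`, `demo`, `all`. Outputs are TSV/JSON files plus a
`manifest.json` recording configuration and seed; reruns with the same seed
are byte-identical.

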