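# Methods

## Model and assumptions

At a heterozygous site in a genome with `c` copies, of which `d` carry
the locally most abundant allele, sequencing reads sample that allele
with probability ≈ d/c. The dominant allele balance (reads of the most
abundant allele over reads of the two most abundant) is therefore
binomially distributed around d/c, and its genome- or window-wide
histogram peaks at 1/2 for diploids, 2/3 for triploid 2:1 sites, 3/4 for
tetraploid 3:1 sites, and so on. The inference inverts this: find the
modal balance per window, match it to the nearest expected ratio, read
off the copy number.

Assumptions this rests on:

- reads sample alleles without bias (no reference bias, no
  allele-specific amplification);
- heterozygous sites are dense enough that a window holds a usable
  number of them (inbred or selfing organisms, and runs of loss of
  heterozygosity, starve the method — such windows are censored by
  `min_count`, not guessed at);
- the genotype caller's het/hom labels are broadly correct (miscalled
  homozygotes put mass at the extremes, which is why balances of exactly
  0 or 1 are refused by `peak_to_ploid` and the `(0, 1]` binning drops
  exact zeros);
- copy number is locally constant at the window scale.

The estimator is deliberately non-parametric. Empirically, balance data
at realistic coverage have a broad noise base spanning almost (0, 1) —
mapping artifacts, paralogy, index hopping — and fit simple parametric
families poorly, particularly at low depth. A histogram mode is cheap,
transparent and robust to that base; the cost is quantization, discussed
below. Mixture-model approaches (beta-binomial, Gaussian, with or
without a uniform noise component) are the parametric alternatives and
are intentionally out of scope.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `window_size` | 40 000 | bases | resolution vs. support trade-off; at ~5 het sites/kbp a window holds ~200 variants. Larger, sparser genomes need larger windows (200 kbp suits a draft oomycete assembly). |
| `bin_width` | 0.02 | balance | histogram resolution. The smallest gap between adjacent expectations is 1/4 − 1/5 = 0.05; 0.02 keeps ≥ 2 bins between any two expectations while leaving ~4+ variants per occupied bin in a typical window. Must be in (0, 0.5]. |
| `min_count` | 20 | variants | least support for reporting a peak; windows below it report their count but no peak. |
| `depth_quantiles` | off; (0.05, 0.95) when enabled | — | per-sample censoring of cells whose total depth falls outside these empirical quantiles, trimming the characteristic long tails at both coverage extremes. Per sample because samples differ systematically in coverage. |
| `max_dfe` | off | — | optional removal of border-case calls; 0 keeps only exact matches, 1 keeps everything. |

All are exposed both in `PloidyScan.fit()` and as CLI flags.

## Numerical choices

- **Bins** are half-open `(lo, hi]` over (0, 1]; a balance of exactly
  1/2 falls in the bin ending at 0.5, a balance of exactly 0 (impossible
  for a genuine het) in no bin. When `1/bin_width` is not integral the
  last bin is truncated at 1 and its midpoint computed accordingly.
- **Peak** = midpoint of the most occupied bin; the midpoint minimizes
  the worst-case discretization error (`bin_width/2`).
- **Ties** between equally occupied bins go to the bin whose midpoint is
  nearest 1/2, then to the lower bin — deterministic, and biased toward
  the commonest (diploid) state. The reference R implementation (vcfR)
  instead takes the leftmost tied bin by default; on tie-free windows
  the two implementations agree exactly (cross-checked in the test
  suite), on tied windows they may differ by design.
- **Windows** are anchored at position 1 of every chromosome (window k =
  `[k·size+1, (k+1)·size]`, 1-based inclusive), so windows are identical
  across samples and runs; no window spans a chromosome boundary.
- **Critical values** are the midpoints {9/40, 7/24, 5/12, 7/12, 17/24,
  31/40} between adjacent expectations; at a critical value the interval
  nearer 1/2 owns the point. Peaks below 7/40 or above 33/40 — a
  half-gap beyond the extreme expectations, nearer homozygosity than any
  supported ratio — get no call. Ratios beyond 1/5–4/5 (copy number
  > 5) are not emitted.
- **dfe** is |peak − expectation| divided by the gap from the
  expectation to the flanking critical value *on the side where the peak
  lies* (the gaps are asymmetric for 1/3, 1/4, 2/3, 3/4). We report the
  magnitude in [0, 1]; vcfR reports the signed ratio, identical in
  absolute value.
- **Known ambiguity**: a dominant peak at exactly 1/2 is called copy
  number 2, although 1/2 is also the central tetraploid (2:2)
  expectation. A tetraploid shows itself through flanking 1/4 / 3/4
  peaks; a single modal bin cannot distinguish the central case, and no
  attempt is made to.
- **Quantization near 1/2**: the diploid expectation sits on a bin edge
  while the folded dominant balance (≥ 1/2 by construction) splits its
  mass between the first bins above it, so with a few hundred variants
  the modal bin can be either of the first two bins above 1/2. Peak
  locations for diploid windows are best read to bin resolution, and
  copy-number calls (which only need the peak inside [5/12, 7/12]) are
  unaffected.

## Differentiation statistics

Per variant, with allele counts n_k observed in population k and weights
w_k = n_k/Σn:

    Hs_k  = 1 − Σ_i p_ki²           (within-population gene diversity)
    Hs    = Σ_k w_k Hs_k
    p̄_i   = Σ_k w_k p_ki
    Ht    = 1 − Σ_i p̄_i²
    Gst   = (Ht − Hs)/Ht
    Htmax = 1 − Σ_k w_k² (1 − Hs_k)
    Gstmax = (Htmax − Hs)/Htmax
    G'st  = Gst/Gstmax

Weighting by *observed alleles* rather than by sample size corrects
simultaneously for unbalanced sampling and for ploidy differences: a
tetraploid population of ten fully-called samples contributes 40 alleles
where a diploid one contributes 20. `Htmax` is the total diversity that
would obtain if no allele were shared between populations (the
cross-population terms of Σp̄² are replaced by their no-sharing value);
with equal weights over k populations it reduces to Hedrick's
H_T(max) = (k − 1 + Hs)/k, and G'st = Gst/Gstmax is Hedrick's
standardization. Weights are per variant (allele counts vary site by
site with missingness). Monomorphic variants (Ht = 0) yield missing
Gst, not 0; every ratio goes missing only where its own denominator is
zero. Statistics are per-variant; genome-wide summaries (e.g.
ratio-of-averages) are left to the user, who gets a plain DataFrame.
Estimators with explicit sampling-bias correction (Weir–Cockerham) are
out of scope.

## The simulator

`simulate_vcf` emulates the *VCF layer* of a joint-called resequencing
experiment, not reads: per chromosome, heterozygous site positions are
uniform at `het_density` (default 5/kbp, within the 3–8/kbp range
typical of the outcrossing fungal/oomycete genomes this method targets);
per site and sample, total depth is negative binomial
(mean `mean_depth` = 100, shape `depth_shape` = 10, giving the
overdispersed, long-tailed coverage real data show) and the dominant
(REF) allele depth is binomial at the segment's true dosage ratio.
A `noise_fraction` (default 0.05) of site–sample draws uses a uniform
(0, 1) ratio instead, reproducing the broad histogram base of real data.
Ploidy is a per-sample piecewise-constant track of `PloidySegment`s
(copy number 2–5, dominant dosage configurable, default c−1), so
sub-genomic CNV is simulated directly and the per-window majority truth
is available from `SimulatedTruth.window_truth`. Homozygous filler
sites can be added (`homozygous_fraction`) to exercise the het masking.

What passing tests on these simulations demonstrate: the windowing,
binning, mode and assignment machinery recovers known dosage structure
through the full VCF round trip, at realistic depth, density and noise.
What they do not demonstrate: robustness to mapping artifacts, reference
bias, linkage, caller-specific AD quirks or mis-specified het calls —
properties of real pipelines that no VCF-level simulation exercises.

Determinism: one `numpy` generator seeded from `SimulationConfig.seed`
drives every draw in a fixed order, so equal seeds give byte-identical
VCFs.

## Design notes

- The package is organised as model objects: `PloidyScan` (data +
  `fit()` → `PloidyScanResults` with estimates, dfe confidences,
  `summary()`, `plot()`, TSV export) and `PopulationDifferentiation` →
  `DifferentiationResults`. The underlying functional modules remain
  importable directly.
- VCF parsing is delegated to pysam; GT/AD are re-serialised to the raw
  string matrices the method operates on. The missing-cell sentinel is
  `pd.NA`/`nan`, never the string `"."`; zero depth is data, missing is
  absence. An AD value of `"."` is treated as missing like an absent AD
  key.
- Depth censoring is applied after het masking, so the quantiles
  describe the heterozygous cells actually analysed. The alternative
  (censor first) shifts quantiles by including homozygous cells; this
  choice is a potential divergence from other implementations and is
  surfaced here deliberately.
- Half-missing genotypes (`"./1"`) are classified non-heterozygous: one
  allele class observed.
- Problem sizes in the test and acceptance runs (1–1.2 Mbp chromosomes,
  ~5 000 sites, 25–30 windows, 500-site single-window dosage checks)
  were chosen as the smallest scales at which every window retains
  ~200 variants of support — the same support a practitioner would
  demand — while keeping the full suite fast.

## Limitations

- No probabilistic uncertainty on the copy-number call beyond dfe; no
  mixture modelling; no use of absolute sequence depth (which carries
  complementary CNV signal) — integration of depth and balance is the
  natural extension.
- Copy numbers above 5 are not called; balanced higher states (e.g.
  hexaploid 3:3) are indistinguishable from diploid at the balance
  level.
- Windows mixing two copy-number states (breakpoints mid-window) yield
  whichever state dominates the histogram, with an elevated dfe.
- The differentiation table carries no significance testing; permutation
  machinery is out of scope.
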