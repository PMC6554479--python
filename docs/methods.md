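# Methods

## Signals

All analyses operate on per-window feature counts over non-overlapping
windows tiling `[0, chrom_length)` (default 10 kb, the resolution at which
pericentromeric structure is visible without drowning kb-scale noise).
Coordinates are 0-based half-open internally; VCF (1-based), GFF3 (1-based
inclusive) and BLAST outfmt-6 subject coordinates (1-based inclusive,
reverse-strand hits with start > end) are converted on ingestion. The last
window of a chromosome may be short; its count is kept raw (window lengths
are exposed for callers that want to normalize — nothing downstream
assumes equal-length windows, and the centromere never sits in the last
window of a real chromosome).

Four counting rules cover the input types:

- **point counts** (SNP sites): a position increments exactly one window;
- **read counts** (mapped-read intervals, the MeDIP-seq methylation proxy):
  any-overlap semantics — a boundary-spanning read increments every window
  it touches, matching `bedtools intersect -c`; a midpoint rule is
  available for sensitivity checks because upstream read-counting
  conventions are not always documented;
- **positional coverage** (genes, BLAST hits): bp covered by the *union* of
  the intervals per window, so overlapping gene models or hits never count
  a base twice; gene bodies are taken from GFF3 `gene` features, not exons;
- **gap counts**: `N`/`n` characters per window of the assembly sequence.

Out-of-range features are dropped with a logged count rather than raised,
to tolerate annotation/assembly version drift.

## Continuous wavelet transform

The Ricker (Mexican-hat) wavelet ψ(u) = (1 − u²)·exp(−u²/2) is zero-mean
and symmetric, so the coefficient W(s, τ) — the correlation of the signal
with ψ scaled to width s and centered at τ — is sign-coded: positive at
peaks of width ~s, negative at valleys, zero on locally constant signal.

Numerical choices, all recorded in output metadata:

- **Normalization.** The per-scale prefactor is s^(−1/2) (unit-energy
  wavelets, `norm="l2"`, default) or 1/s (`norm="l1"`). Within a scale the
  two differ by a positive constant, so every within-scale decision the
  caller makes (argmax, argmin, zero crossings) is identical under both;
  only cross-scale comparisons (scale selection) can differ, which is why
  the option is logged and the caller's stability across both is tested.
- **Scale grid.** Dyadic with 8 voices per octave from 2 windows up to a
  quarter of the signal length — the largest scale whose boundary padding
  still fits. Scales too large for a given signal are dropped with a
  warning rather than extrapolated.
- **Boundary rule.** The signal is padded by 4× the largest scale with a
  mirror reflection (default) or zeros, transformed, and cropped.
  Reflection avoids the spurious edge valleys that zero padding creates at
  telomeres (a step edge looks like half a valley); zero padding is kept as
  an option because the stability of calls under both is itself a useful
  diagnostic. With reflection, any coefficient at least 4s from a
  chromosome end is provably unaffected by the rule.
- **Support truncation.** The wavelet is evaluated on |t| ≤ 8s; beyond
  that its amplitude is < 1e−13 of the peak, so truncation error is far
  below the 1e−8 interior-annihilation tolerance asserted in tests.
- The transform is computed by FFT convolution per scale; an explicit-loop
  quadrature implementation exists in the test suite as an independent
  oracle (relative agreement 1e−6, observed ~1e−13).

## Centromere caller

Inputs are the methylation and SNP density profiles of one chromosome,
standardized to mean 0 / sd 1 before the transform so amplitudes are
comparable across data types (calls are therefore invariant to positive
rescaling of either input). With M the methylation landscape and S the SNP
landscape (rows ascending in scale):

1. The **pericentromeric scale** p and peak position are the argmax of the
   coefficients over the top third of the scale rows (rows with index
   ≥ ⌈2·n_scales/3⌉ — the split is over grid rows, scales being
   log-spaced). Restricting to the top third keeps the search on broad,
   chromosome-arm-scale structure.
2. **Pericentromere borders** b₁, b₂ are the nearest windows at or below /
   above the peak where M_p ≤ 0 (exact zeros count as crossings; window
   resolution, no interpolation). A side with no crossing falls back to the
   chromosome end and sets a qc flag. A non-positive coefficient *at* the
   peak is a degenerate signature and yields a structured no-call.
3. The **centromeric scale** c is the argmin over the lower two-thirds of
   S's rows, columns restricted to [b₁, b₂]: the narrow valley must sit
   inside the pericentromere.
4. The **center** is the argmax over x ∈ [b₁, b₂] of M*_p,x − S*_c,x
   (standardized vectors; ties break to the smaller x and are logged). A
   `--search global` knob lifts the [b₁, b₂] restriction for comparison;
   on clean signatures both agree. The **general centromeric region** spans
   to the first sign change of the standardized difference on each side of
   the center, clipped to [b₁, b₂] with qc flags if absent. **D** is the
   difference of the *unscaled* coefficients at the center — an
   interpretable signature strength in coefficient units, whereas the
   center itself is located on standardized curves.

p_scale > c_scale is expected of a true signature but enforced only as a
qc warning (`scale_order`), since a legitimate landscape could violate it.
Degenerate chromosomes (flat profiles, all-negative methylation top third)
produce a no-call record with qc flags, never an exception, so multi-
chromosome runs complete. Reported `center_bp` is the midpoint of the
called window; the method's resolution is one window (10 kb) by
construction.

## CCC co-segregation

Genotypes are ALT-allele dosages {0, 1, 2} with missing calls preserved.
Sites are filtered at MAF > 0.01 *and* call rate > 0.5 — strict
inequalities, so a site exactly at a boundary is removed. For a pair of
alleles at two sites, all quantities are computed over the individuals
non-missing at *both* sites: frequencies measured on all individuals would
let differential missingness inflate correlations. Pairs with fewer than
100 overlapping individuals are suppressed (reported as below-overlap, not
scored zero).

CCC = (9/2) · R · (1 − f_ix)(1 − f_jy). Two genuinely open conventions are
implemented as options and stamped into output metadata:

- **Frequency penalty.** Default (1 − f): CCC is then non-negative and a
  monomorphic allele scores 0, as an allele-specific association measure
  should. The alternative (1 − 1/f) reading is selectable
  (`reading="one_minus_inv_f"`); its two negative factors multiply to a
  positive penalty that *rewards* rare alleles much more aggressively.
- **Co-occurrence rule for unphased diploids.** Default is the carrier
  rule: R = fraction of overlap individuals carrying ≥ 1 copy of both
  alleles. Under Hardy–Weinberg a perfectly co-segregating pair at MAF
  0.2–0.5 then scores CCC ≈ 0.84–1.12, comfortably above the 0.7 edge
  threshold, while independent pairs stay below ≈ 0.66. The dosage rule
  R = Σ min(d_x, d_y)/(2n) ("maximal pairing without phase") is selectable,
  but note its ceiling under the (1 − f) penalty is 4.5·f·(1 − f)² ≤ 2/3 —
  *no* pair, however perfectly co-segregating, can reach 0.7 — so it is a
  graded LD measure to be used with its own threshold, not the default one.
  This ceiling is why the carrier rule is the default.

All four allele pairings of a site pair are evaluated; every pairing that
clears the threshold is reported once. The all-pairs scan can be
partitioned into contiguous near-equal site blocks with one job per
within-block and per unordered cross-block comparison (n + n(n−1)/2 jobs;
20 blocks → 210). The partition exists for parallel deployment at
population scale; here the jobs run serially and the tests verify the jobs
cover every site pair exactly once.

`coevolution_profile` counts, per window, the distinct SNPs outside an
anchor interval that share at least one above-threshold edge with a SNP
inside it — a SNP with several anchor partners counts once.

## Synthetic generator

`CentromereScenario` emulates one chromosome's window counts with
closed-form expectations: methylation β_m + A_p·G(μ, σ_p) − A_d·G(μ, σ_c)
(broad peak, narrow central dip; G a unit-height Gaussian), SNP density
β_s − B·G(μ, σ_c) (the medium-scale centromeric valley that the caller's
centromeric-scale step is built to find; an optional shoulder term adds the
broad pericentromeric SNP elevation of the full signature), gene coverage
β_g − C·G(μ, σ_p). Realized counts are Poisson around the expectation —
the natural noise for window counts — with an optional negative-binomial
overdispersion knob (`overdispersion=r` gives variance λ(1 + λ/r)) for
robustness experiments. Assembly-gap runs force all signals to zero and
fill the gap profile. Defaults: 2000 windows of 10 kb (a mid-sized
chromosome), center at window 800, σ_p = 150 and σ_c = 25 windows,
baselines/amplitudes (100 + 200 − 120 methylation reads, 80 − 60 SNPs,
5000 − 4500 gene bp per window) in the range typical of 10 kb windows in a
densely genotyped plant panel.

`LDScenario` plants LD blocks in a genotype matrix: each block draws one
latent haplotype pair per individual at the block's MAF under
Hardy–Weinberg, every SNP in the block copies the latent haplotypes with
per-allele flip probability ε, and cells are masked missing at a fixed
rate. Blocks are independent unless explicitly linked (sharing a latent),
which emulates a gene anchor co-evolving with a distal region. Defaults —
200 individuals, three 8-SNP blocks at MAFs 0.25/0.20/0.30, ε = 0.01,
10% missing — give pairwise overlaps ≈ 162 (above the 100 floor) and
within-block CCC well above / cross-block well below the 0.7 threshold.

What the generator does *not* emulate, and hence what passing tests do not
show about real data: centromere shapes are exactly Gaussian (no asymmetric
or bimodal pericentromeres, no holocentric chromosomes), noise is
independent across windows (no mappability waves or copy-number artifacts),
genotypes have no population structure, relatedness or recombination-map
realism, and missingness is uniform rather than depth-dependent. The
recovery numbers (center within ±2 windows in ≥ 18/20 default-scenario
seeds; sweep median error ≤ 2 windows) characterize the algorithm under
these idealized conditions, not expected accuracy on real chromosomes.

## Problem sizes

Test-suite and acceptance-script simulations use 2000-window chromosomes,
a 27-scenario × 10-seed recovery sweep, 20 default-scenario seeds,
30-site × 50-individual matrices for the exhaustive scan oracle and
24-site × 200-individual matrices for LD recovery — sizes chosen so the
full suite and the acceptance script each complete in well under a minute
per stage on one CPU while leaving the statistical assertions
comfortable margins.

## Known limitations

- Window-resolution output: centers and borders are reported at 10 kb
  granularity; no sub-window interpolation is attempted.
- The caller assumes one centromere per chromosome (monocentric); a
  chromosome with two comparable signatures yields the stronger one only.
- The upper-third / lower-two-thirds scale split is defined over grid rows;
  a very different scale-grid density would shift the effective scale
  ranges (the dyadic 8-voice default is part of the method's definition
  here).
- The serial CCC scan is quadratic in sites; the block schedule is the
  hook for distributing it, but no parallel executor is shipped.
- MeDIP-seq read density proxies methylation; the caller is agnostic to
  tissue and to the proxy's biases (CpG density, mappability).
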