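# Methods

`oligocna` implements an allele-specific copy-number analysis for SNP-array
data from tumor/blood pairs, of the kind used to characterize anaplastic
oligodendroglioma cohorts: preprocessing of Log R Ratio (LRR) and B-allele
frequency (BAF) tracks, a six-state hidden Markov model whose parameter
constraints track a running tumor-purity estimate, and cohort-level event
and association analysis. This note records the model, its assumptions,
the tunable parameters, and the design decisions taken where the design
was genuinely open.

## Signal model

A sample is a mixture of a tumor clone (fraction `p`, the purity) and
normal cells (fraction `1 - p`). For a locus with tumor total copy number
`c`, tumor B-allele count `nB`, and germline B-allele count `gB ∈ {0,1,2}`:

```
E[BAF] = (p·nB + (1-p)·gB) / (p·c + 2(1-p))          (band center)
E[LRR] = s0 + log2( max(p·c + 2(1-p), 0.1) / 2 )      (state mean)
```

`s0` is a sample-level baseline shift; the 0.1 effective-copy floor keeps
the homozygous-deletion mean finite as `p → 1`. Both formulas live in
`oligocna.synthetic` and are shared verbatim by the simulator (which emits
from them) and the HMM (which inverts them), so purity recovery tests are
exact checks of the inversion, not of two separately coded models.

Six states realize the categories a tumor-genomics analysis reports:

| state  | c | het BAF bands at purity p        |
|--------|---|----------------------------------|
| HOMDEL | 0 | uninformative (uniform)          |
| LOSS   | 1 | (1-p)/(2-p), mirrored            |
| NORMAL | 2 | 0.5                              |
| CNLOH  | 2 | (1-p)/2, mirrored                |
| GAIN   | 3 | 1/(p+2), mirrored                |
| AMP    | 4 | 1/(2+2p), mirrored               |

NORMAL and CNLOH share `c = 2` and are separated only by BAF — this is
what makes copy-neutral LOH (uniparental disomy) invisible to pure
copy-number analysis and visible here. AMP is modeled at `c = 4` with
both extra copies on one allele (`nB ∈ {1,3}` for a het germline);
higher-level amplification is a post-hoc label (below). For homozygous
germlines the band centers reduce to exactly 0 and 1 under every
non-HOMDEL state, so heterozygous probes carry all allelic information.

## Synthetic data generator

The generator stands in for the patient cohort (no array data were
deposited) and emulates Illumina-style paired tracks:

- **Scaffold** — per chromosome, uniform-random positions over
  GRCh37-scale lengths; GC fraction as a moving average of white noise
  clipped to [0.3, 0.7]; population B-allele frequency from a symmetric
  Beta(0.9, 0.9), giving a ~32% heterozygote rate under Hardy–Weinberg.
- **Blood** — BAF at the genotype mean plus truncated-Gaussian noise;
  LRR pure Gaussian noise.
- **Tumor** — LRR = state mean + linear GC wave
  (`gc_wave_amp · (gc − mean gc)`) + Gaussian noise; BAF = band center +
  truncated-Gaussian noise, with a uniform outlier fraction; HOMDEL BAF
  uniform. The affected allele (band branch) is drawn per probe, which
  reproduces the mirrored-band appearance of real data.
- **Shared BAF noise** — tumor and blood BAF noise share a common
  component (correlation 0.75). This is the situation TumorBoost exploits;
  without it paired correction could only add noise. Tumor and blood LRR
  noise are independent, so paired LRR normalization costs √2 in noise
  here — on real data it removes shared probe-level artifacts the
  generator does not model.

Noise defaults (`lrr_sd = 0.18`, `baf_sd = 0.04`, `outlier_rate = 0.02`,
`gc_wave_amp = 0.3`) are calibration choices in the range of what Illumina
tumor arrays show, not measured values. Scenario templates mirror the
tumor classes of an oligodendroglioma cohort: `codel` (whole-arm 1p and
19q loss abutting the centromere edges — the t(1;19)(q10;p10) surrogate),
`codel_9p_cnloh`, `codel_cdkn2a_homdel` (focal ≥10-probe homozygous
deletion anchored at a fixed CDKN2A-like locus on 9p so that the event
recurs across carriers), `astro_like` (focal EGFR-like 7p amplification,
whole-chromosome-10 loss, 17p CNLOH) and `flat_normal`.

What the generator does **not** emulate: probe-specific bias and wave
structure beyond the linear GC term, genotyping error in the blood,
subclonal (fractional) events, segmental artifacts near centromeres, and
X-chromosome ploidy (simulated scaffolds are autosomal). Passing tests
therefore demonstrate correctness of the inference machinery under the
stated mixture model, not robustness to every real-array artifact.

## Preprocessing

1. **GC-wave correction** — least-squares fit of LRR on (gc, gc²); the
   fitted component is subtracted and the track re-centered to preserve
   the pre-correction median. A quadratic closed form was chosen over
   loess: deterministic, testable, and sufficient for the linear wave the
   generator produces.
2. **Reference normalization** — tumor LRR minus the paired blood LRR, or
   minus the per-probe median of ≥3 same-platform blood samples when no
   pair exists.
3. **Genotype calling** — thresholds on blood BAF: <0.15 AA, >0.85 BB,
   [0.25, 0.75] AB, guard bands uncalled. The guard bands trade call rate
   for purity of the heterozygous set, which drives purity estimation.
4. **TumorBoost-style BAF rescaling** — multiplicative variant: with
   `μ ∈ {0, ½, 1}` the germline expectation, the side of the tumor BAF
   below/above the blood BAF is rescaled by `μ/normal` or
   `(1-μ)/(1-normal)`. This variant preserves [0,1] without interior
   clipping; the published algorithm's flavor is not uniquely specified,
   so the acceptance surface is the variance-reduction property, not
   formula identity.

## HMM inference

**Emissions.** Per probe and state: a Gaussian LRR term (per-state mean
and SD) times a BAF mixture over germline genotype (the called genotype
when available, Hardy–Weinberg priors from the population frequency
otherwise) and band branch (equal weights), using truncated Gaussians on
[0,1], plus a uniform outlier component with weight `π_o`. HOMDEL's BAF
term is uniform. Missing BAF or LRR drops the corresponding term.

**Transitions.** `A(d) = ρI + (1-ρ)·1πᵀ` with `ρ = exp(-d/L)`,
`L = 5 Mb` by default; chromosomes are independent. This distance-decay
family makes the forward/backward recursions O(states) per probe, which
the numba kernels exploit.

**Purity-adaptive bounds.** The free emission parameters — per-state LRR
means and heterozygous band deviations — are box-constrained to
`formula(p̂) ± δ` (`δ = 0.15` LRR units, `0.05` BAF units), and the boxes
are **recomputed every iteration** around the current purity estimate,
with out-of-box parameters projected onto the nearest bound. Purity
itself is re-estimated each iteration by inverting the band geometry on
posterior-weighted folded het BAF per aberrant state
(LOSS: `p = (1-2b)/(1-b)`; CNLOH: `p = 1-2b`; GAIN: `p = 1/b - 2`),
combining states with ≥5 effective het probes by inverse delta-method
variance, clipped to [0.05, 1]. Samples with no aberrant mass keep their
input purity and are flagged unidentifiable. Moving the boxes rather than
fixing them is what lets low-purity samples converge to compressed bands
instead of collapsing onto the all-normal solution.

**EM loop.** E-step by scaled forward–backward; M-step closed forms for
state means/SDs, band deviations, `s0`, `σ_BAF`, `π_o` (capped at 0.3)
and the stationary probabilities, all projected into the current boxes;
then the purity update and box recentering. Because the box move is not
an exact EM step, an update that would lower the log-likelihood is
rejected and that start terminates — the accepted log-likelihood sequence
is non-decreasing by construction (verified to 1e-8 relative tolerance).
Convergence at 1e-6 relative change or 100 iterations. Multi-start over
`p₀ ∈ {0.3, 0.5, 0.7, 0.9}` combats the `p ↔ band-mirror` ambiguity;
likelihood ties break toward the larger start (the high-purity reading).
Decoding is Viterbi under the final parameters.

**Segments.** Maximal constant-state runs; runs of fewer than 10 probes
are absorbed into the flanking neighbor with the higher mean posterior
over the run (repeatedly, smallest run first, leftmost on ties) until all
segments have ≥10 probes. Chromosomes with <10 probes become one flagged
segment.

## Event calling

- **Arm calls** — probe-weighted state fractions per arm; loss/gain need
  ≥90% of arm probes (`θ_arm`, the "whole-chromosome-arm" convention),
  CNLOH ≥50% (`θ_cnloh`, realizing "large CNLOH"). Both thresholds are
  conventions; the source analyses never quantify them.
- **Co-deletion class** — `codel` requires whole-arm 1p loss + 19q loss,
  neutral 1q and 19p, and a centromeric breakpoint on both chromosomes
  within 3 Mb (a whole-arm segment abutting the centromere edge counts).
  Isolated 1p or 19q whole-arm loss without the partner is the "false
  co-deletion" pattern and is classed separately.
- **Breakpoints** — midpoint (floor) between flanking probes of adjacent
  same-chromosome segments with differing states. Cross-tumor loci by
  greedy nearest-locus clustering with 1 Mb tolerance (position-sorted;
  join the nearest running-mean locus within tolerance, else found one).
- **Recurrent regions** — sweep-line over HOMDEL/AMP segment endpoints;
  maximal intervals with coverage ≥ k (k = 2), annotated with overlapping
  genes from a BED.
- **High-level amplification** — AMP segments whose mean LRR exceeds the
  5-copy expectation at the fitted purity.
- **Clustering** — per-tumor total-copy vectors over 1 Mb bins (CNLOH → 2,
  so clustering reflects copy number only), Euclidean distance, average
  linkage, deterministic leaf order by sample id, exported as an
  ultrametric Newick tree.

A consistency requirement ties the synthetic probe density to the 3 Mb
centromeric tolerance: boundary placement error is of the order of the
local inter-heterozygous-probe spacing (homozygous probes carry no
allelic signal), so scaffolds must be dense enough that this spacing is
well under the tolerance. The shipped cohort uses 250 probes per
chromosome (~0.5–1 Mb spacing, ~70× sparser than a 370k array); at ~2 Mb
spacing the breakpoint surrogate becomes unreliable at low purity by
construction.

## Cohort statistics

Fisher's exact test (two-sided, probability-mass rule) for event ×
categorical-variable tables; Welch's t (the safer default where the
pooled/unpooled choice is unstated — recorded in output metadata) for
quantitative variables; Benjamini–Hochberg control applied per phenotype
variable across events (the family choice is likewise recorded);
Yates-corrected χ² with the correction clamped at zero; Kaplan–Meier
product-limit curves with median = earliest `t` with `S(t) ≤ 0.5`; and a
two-group log-rank test exposing its O/E/V decomposition. Fisher, Welch,
KM and BH delegate to scipy/lifelines/statsmodels; Yates and log-rank are
computed directly (the clamped correction and the O/E/V components are
needed) and cross-checked against the library implementations in tests.

## qPCR copy-number validation

`copies = 2 · 2^(−ΔΔCt)` with duplicates averaged, assuming a diploid
calibrator and a diploid reference locus (RNase P-style). Failed target
amplification (Ct ≥ 45) with an intact reference reports copies < 0.5
with a homozygous-deletion-consistent flag. Class cut-offs
(0.5/1.5/2.5/5) are conventional and stated in output metadata.

## Problem sizes and determinism

The test suite and the acceptance script regenerate everything from
seeds: recovery runs use 20 tumors × ~10,000 probes (purities 0.5–0.95,
default noise), the discrimination cohort 15 tumors × 5,500 probes, and
the exactness oracle enumerates all state paths on ≤8-probe chains. All
randomness flows through `numpy.random.default_rng` children of a single
seed; identical seeds give bit-identical outputs.

## Known limitations

- No subclonal states: every aberration is assumed clonal at purity `p`.
- Purity is driven by BAF band geometry only; a sample whose only events
  are homozygous deletions has unidentifiable purity.
- The genome build behind the packaged arm table is a configuration
  item; analyses tied to exact base-pair coordinates must supply their
  own arm/centromere table.
- Cohort-median normalization (no paired blood) leaves BAF uncorrected;
  CNLOH detection is then limited to grossly separated bands.
- The X chromosome is carried through I/O but the shipped simulator and
  recovery studies are autosomal; no male/female ploidy handling.
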