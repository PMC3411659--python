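# Methods

## The screen as a chain of sampling bottlenecks

A pooled shRNA viability screen measures, for each hairpin *i* in a pool of
size S, the change in relative abundance between a reference sample T0
(taken after initial selection of transduced cells) and a test sample T1
(taken after a further 14 days of selection). `poolscreen` models the
pipeline as a sequence of conditional sampling steps, each with an explicit
distributional form:

1. **Plasmid pool.** Per-hairpin proportions p_i; real pools are skewed, so
   the generator draws them log-normally (σ = 0.35 by default, see below).
2. **Transduction.** N = round(S·C) integrations ~ Multinomial(N, p),
   where C is the fold representation (100 or 500 in the study
   conditions). The MOI (0.3) is carried only to justify the
   one-integration-per-genome accounting; infection kinetics are not
   modeled, because coverage — not virology — is what the protocol
   reports and controls.
3. **Selection.** Each day, n_i ← Poisson(n_i · exp(g0 + f_i)) with
   baseline growth g0 = ln 2 per day and per-hairpin fitness effect f_i
   (per day). Whenever the population exceeds `passage_trigger` (4×) times
   its starting size it is passaged by binomial thinning with
   `passage_ratio` (1:4). The expected relative abundance after d days is
   ∝ n_i(0)·exp(f_i·d), so a fitness of −0.3/day over 14 days depletes a
   hairpin by e^−4.2 ≈ 0.015 relative to neutral hairpins. Fitness
   effects default to a point mass at 0 for 95% of hairpins and
   Normal(0, 0.1/day) for the rest — an affected-minority prior whose
   14-day log2 fold changes spread over ≈ ±2, the range the hit rule
   targets; the study gives no effect-size distribution, so this is a
   package choice, and a user table overrides it.
4. **gDNA aliquot.** round(S·T) template molecules ~ Multinomial over the
   cell-population proportions, where T is the average template copies per
   hairpin. This is the step the gDNA arithmetic (below) budgets for.
5. **PCR.** A per-molecule Galton-Watson branching process: at each cycle
   every molecule of hairpin *i* duplicates with probability
   e_i · sat(total). The saturation law sat = min(1, K/total) gives a
   sharp exponential-to-linear transition (a logistic alternative
   K/(K+total) sits behind a switch); no functional form is published, and
   the step law was chosen because it reproduces the observed abrupt end
   of doubling near a specific cycle. When no explicit capacity is given,
   K = input_total · 2^23, encoding a protocol that fixes template mass
   per reaction tube so the exponential phase ends near cycle 23
   regardless of how many tubes are run. e_i is the tube's per-clone
   efficiency: e0 (0.98 by default — near-100%-efficient high-fidelity
   chemistry) times a per-tube, per-clone relative jitter
   (σ = 0.01), modeling sequence-context amplification bias that
   compounds over cycles. Two consequences match the bench observations:
   log-ratio noise between technical replicates falls as template copies
   rise (Poisson 1/√T at the aliquot, Galton-Watson 1/n0 in early
   cycles), and grows with cycle count past saturation.
6. **Readout.** Sequencing: reads ~ Multinomial(depth, proportions), with
   optional FASTQ emission of error-free 50-bp reads for the counting
   round-trip. Microarray: per-probe log2 intensities
   log2(proportion·scale) + Normal(0, σ_array), floored at the
   background, `array_probes_per_clone` probes per clone and channel.

All randomness flows from one master seed through named SHA-256-derived
substreams: biological replicates re-draw transduction and selection,
technical replicates re-draw only aliquot, PCR and readout. Seeded runs
are bit-reproducible.

### What the generator does and does not emulate

It reproduces the *sampling structure* of a screen — coverage, selection
dynamics with passaging, template budgets, PCR saturation and per-tube
bias, finite read depth, probe-level array noise. It does not model
off-target silencing, knockdown-efficiency differences between hairpins,
multi-integration cells, cell-cycle structure, sequencing error, or array
spatial artifacts. Passing tests therefore demonstrate that the analysis
stack behaves correctly under the stated noise mechanisms, and that the
orderings (more template ⇒ more reproducible; more coverage ⇒ more
reproducible; fewer post-saturation cycles ⇒ tighter abundance range) are
consequences of those mechanisms — not that real screens have any
particular R value. Published correlation values depend on unmeasured
biological and platform noise and are deliberately not targeted.

## gDNA representation arithmetic

With one integration per genome, template copies in a gDNA mass m are
m / m_g, with genome mass m_g = 6.6 pg by default (diploid human; it can
be derived as B·µ/N_A from a base-pair count B at 650 g/mol/bp). One
825 ng reaction therefore carries 125 000 copies — 12.5 per hairpin for
S = 10 000 — and a plan for C copies per hairpin needs
⌈S·C / copies_per_reaction⌉ reactions. The ceiling is deliberate:
coverage is a floor guarantee, so a partial reaction always rounds up.
Nominal S (10 000) versus exact pool size (10 317/10 353) is a caller
choice; the protocol arithmetic uses nominal.

## Exponential-phase detection

Replicate PCR reactions stopped at cycles 15–27 are diluted (25 000-,
100 000-, 400 000-fold) and re-measured by SYBR qPCR in quadruplicate.
Within each dilution, replicate Cq values are averaged per stop cycle and
the absolute difference between adjacent stop cycles taken; differences
are averaged across dilutions (the dilution factor cancels), divided by
the efficiency correction factor E_c = log_(1+e) 2 (1.38 at 65% primer
efficiency — one observed Cq unit is less than one doubling for
sub-perfect primers), and divided by the panel's cycle step so that
wider-spaced panels read in the same per-cycle doubling units. The last
cycle at which the corrected ΔCq still reaches 1 is the recommended
amplification cycle count.

Numerical choices: the window rule stops at the *first* sub-threshold
pair (the data give no guidance on interior blips); the signed difference
is kept as a diagnostic column while the statistic uses |·| as defined;
replicate aggregation is a plain mean with no outlier rejection. The
default tolerance on the ΔCq ≥ 1 rule is 0.05 cycles; with per-well
replicate noise of σ = 0.1 the averaged series has a standard error of
≈ 0.04 cycles, so recovery tests use a noise-scaled allowance of 0.2
(≈ 5 SE) — at that setting the caller recovers a true transition at
cycle 23 within ±1 cycle in > 95% of seeded panels.

## Deconvolution and presence

Reads are assigned by exact prefix match: a read counts for clone *i* iff
its first `read_len` bases equal clone *i*'s reference prefix (the
sequencing primer anneals immediately adjacent to the hairpin, fixing
position and orientation; zero mismatches). The index build rejects
references sharing a prefix; assigned + unassigned always equals total. A
substring mode exists for unanchored designs. Presence: sequencing calls
a hairpin present above 50 alignments — strictly more than 50 by
default, with a flag for ≥ 50, since the two wordings circulate —
and the array platform uses a one-sided one-sample t-test of
background-subtracted probe intensities against zero at p < 0.05.

## Differential abundance

Counts are normalized by median-of-ratios size factors (per sample, the
median across all-positive hairpins of count over geometric mean). The
test is a conditional exact test under the negative binomial: given a
hairpin's total count k = k0 + k1, the p-value sums the conditional
probabilities of every split (a, k−a), a ~ NB(q·s0, α) and
k−a ~ NB(q·s1, α) with q = k/(s0+s1), that is no more likely than the
observed split. At α = 0 this reduces to the conditional binomial
(e.g. a 5/0 split at equal size factors gives p = 2/32 = 0.0625). Note
that p is not monotone in α: as α → ∞ the conditional distribution
concentrates on extreme splits and interior splits become the unlikely
ones — the implementation follows the definition, and the test suite
asserts the (correct) monotone behavior over moderate dispersions.

Dispersions are method-of-moments per hairpin, α̂ = max(0,
(s² − m̄)/m̄²), on normalized counts — pooled blind across all samples
when each condition has a single library, or within conditions otherwise
— then shrunk toward a local mean–dispersion trend. The trend is a
binned-median local regression: hairpins are binned by log mean (≥ 50
per bin), each bin contributes its median raw estimate divided by the
chi-square median-consistency factor χ²_df.ppf(0.5)/df (a raw estimate
from df+1 samples scales like α·χ²_df/df). The median makes the trend
robust to a minority of true-effect hairpins, whose real abundance change
masquerades as variance under blind pooling and concentrates at the
extremes of the mean axis — a distance-weighted smoother is dominated by
them exactly where power matters. For Poisson data the binned median is
exactly zero, so the trend correctly vanishes; for genuinely
overdispersed data the consistency factor keeps it unbiased (recovery
simulations at α = 0.1 return a median estimate ≈ 0.1). The weight on a
hairpin's own raw estimate is max(0, 1 − 2/m) for m pooled samples: zero
at m = 2, where one degree of freedom carries no usable per-hairpin
information.

Array data are tested per clone with a two-sided Welch t-test on the
probe intensities of the two channels (the platform's own error model is
proprietary; unequal variances are the safe default), with FC the ratio
of mean probe intensities. Both platforms add a 0.5 pseudocount to both
conditions before fold-change and log-ratio computation to keep zeros
finite, apply Benjamini-Hochberg step-up correction, and call hits at
absolute fold change ≥ 2 and adjusted p ≤ 0.05 (both bounds inclusive).
Technical replicates are pooled into one test per biological replicate;
combined analyses pool both biological replicates.

## Reproducibility metrics

Log ratios are log10 of pseudocounted normalized abundances, with an
optional signal filter (arrays drop probes whose T0 signal is below
two-fold median background). Replicate agreement is Pearson R on the
intersection of finite log ratios. Hit overlap reports raw counts plus
percent of the smaller list, 100·|A∩B|/min(|A|,|B|) — the only
denominator convention consistent with every published overlap row — and
the one-sided unique fraction 100·|A∖B|/|A|. The abundance-range
statistic F(q) is the smallest max/min ratio over any ⌈q·n⌉-subset of
positive abundances (q = 0.7 by default); on sorted data the optimum is a
contiguous window, so a sliding-window pass is exact (verified against
exhaustive subset search), and F is scale-invariant.

## Problem sizes and defaults

Simulation-based checks run at S = 2 000 hairpins with 25–100 seeded
runs per comparison; the tested orderings are direction statements whose
truth does not depend on S, and this size keeps the full suite and the
acceptance script fast on one CPU. Study-condition defaults:
C = 100, MOI 0.3, 14 selection days, 1:4 passaging, 23 PCR cycles,
100 template copies per hairpin, 89 M reads per sample (8 900 per
hairpin at S = 10 000). Generator-only defaults chosen by the package:
plasmid skew σ = 0.35 (keeps the plasmid pool's 70% range below
10-fold, as in a well-made library), PCR e0 = 0.98 with per-tube clone
jitter σ = 0.01, array noise 0.25 log2 units with 4 probes per clone.

## Known limitations

The NB machinery is a re-implementation faithful to the test's
definition, not bit-compatible with any particular legacy software
version whose fitting options are unpublished; agreement is established
at the level of type-I error, power and enumeration oracles. The
simulator's noise mechanisms are sufficient, not exhaustive — real
screens add hairpin-specific knockdown variation and platform artifacts
that raise biological scatter; simulated replicate correlations are
therefore optimistic in absolute terms even where their orderings are
robust. The exponential-phase caller assumes the panel's noise is
roughly homoscedastic across stop cycles; heteroscedastic late-cycle
noise would warrant a per-pair tolerance.
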