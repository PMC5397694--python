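# Methods

## Signal model

A cytosine sequenced after bisulphite treatment is *retained* (read as C)
or *converted* (read as T). With per-CpG modification proportions p_5mC
and p_5hmC (p_5mC + p_5hmC ≤ 1), the retention probability per read is

- Bis: r = (p_5mC + p_5hmC)(1 − e_overconv) + (1 − p_5mC − p_5hmC) e_nonconv
- OxBis: r = p_5mC (1 − e_overconv) + p_5hmC (1 − eff_ox) + (1 − p_5mC − p_5hmC) e_nonconv
- TAB: r = p_5hmC · eff_bgt + p_5mC (1 − eff_tet)(1 − e_overconv) + (1 − p_5mC − p_5hmC) e_nonconv

Retained counts are NC ~ Binomial(N, r) at coverage N. The chemistry
parameters, with defaults taken from spike-in measurements:

| parameter | meaning | default |
|---|---|---|
| `e_nonconv` | unmodified C retained (non-conversion error) | 0.0042 |
| `e_overconv` | modified C converted (over-conversion error) | 0.017 |
| `eff_ox` | 5hmC oxidised in OxBis | 0.9933 |
| `eff_tet` | 5mC oxidised in TAB | 0.9874 |
| `eff_bgt` | 5hmC protected in TAB | 1.0 |

`e_overconv` is set from the lower end of the measured Bis conversion
range (98.30%) and applied symmetrically to 5mC and 5hmC, since only
aggregate conversion efficiencies are reported. With perfect chemistry,
Bis reads 5modC and OxBis reads 5mC in expectation; the caller's
subtraction delta = p_Bis − p_OxBis then estimates p_5hmC. With the
default chemistry the true expected difference is
p_5hmC (eff_ox − e_overconv) ≈ 0.976 · p_5hmC — a ~2.4% multiplicative
attenuation the caller does not correct for.

## Synthetic data generator

`sim.simulate_methylome` draws per-CpG (p_5mC, p_5hmC) from per-feature
beta mixtures. Feature labels (TssA, TssAFlnk, Tx, Enh, CGI, Quies) are
assigned in contiguous blocks of ~50 CpGs so interval analyses see
coherent territories; positions follow geometric gaps (mean 100 bp) on
one synthetic chromosome. The defaults encode the qualitative genomic
5hmC landscape — enhancers and transcribed regions carry the highest
5hmC (beta means 0.20 and 0.15), promoters and CpG islands are depleted
— because no generative description of the real landscape is available;
these means are a modelling choice, exposed in the configuration. p_5hmC
is drawn first and p_5mC capped at 1 − p_5hmC, so the 5hmC marginal
keeps its configured beta mean exactly.

Coverage is Poisson per treatment, drawn independently for Bis and OxBis
(they are separate libraries); the default means are the study's 18×/16×.
Array betas are the chemistry-adjusted retention expectation plus
clamped Gaussian noise (default SD 0.02, two replicates per treatment).
hMeDIP input counts are Poisson with mean 15 per 300-bp tile; IP counts
are negative-binomial (dispersion 0.01, matching the analysis
assumption) with mean scaled by an enrichment function of tile-average
true 5hmC (default affine, 10× at full hydroxymethylation). Spike-in
controls contribute fully modified sites plus unmodified sites per
assay. Amplicon reads interpolate between all-or-none molecules and
independent per-CpG sampling via the `mosaicity` parameter.

What the generator does **not** emulate: read-level artefacts
(alignment, PCR duplicates, strand effects), array probe-design biases
(type I/II chemistry), coverage autocorrelation along the genome, and
any realistic joint distribution of 5mC and 5hmC beyond the beta
mixtures. Tests passing on this generator demonstrate statistical
correctness of the pipeline under its own model assumptions, not
robustness to those real-data artefacts.

## Single-base caller

Per CpG (with ≥ 10× in *both* treatments — CpGs failing either arm are
excluded), the 2×2 retained/converted table is tested with the
chi-square two-proportion test with Yates continuity correction, the
correction capped at |delta|/(1/N_Bis + 1/N_OxBis); this reproduces R's
`prop.test` to machine precision (validated against frozen reference
values). A CpG is significant when the two-sided p < 0.05 *and*
delta > 0; no multiple-testing correction is applied at this stage (a BH
option exists but is off by default). Under a 5hmC-free null the
one-sided condition makes the expected call rate ≈ α/2, and the Yates
correction pushes it lower still at moderate coverage (~1% observed at
30×).

Region averages use the discard/impute rules: significant CpGs
contribute delta; non-significant CpGs with 0 ≤ delta ≤ 0.10 are imputed
to zero; non-significant CpGs with delta > 0.10 (too noisy to trust) and
all CpGs with delta < 0 (chemically impossible) are discarded. The
boundary delta = 0.10 imputes to zero. Averages run over contributing
CpGs only; regions with none are flagged undefined.

`power_two_proportion` is the closed-form normal-approximation power of
the *uncorrected* two-sided test (equal group sizes), matching the
standard power calculation; it matches the Monte-Carlo rejection rate of
the uncorrected test within 0.01 at (0.8, 0.7, n = 60). The
Yates-corrected test is more conservative (~0.185 vs 0.242 there), which
is why the correction is configurable.

## Array differential analysis

Probes need detection p < 0.01 in all samples. Betas are capped at
[0.01, 0.99] and logit-transformed; log base 2 is used (the standard
M-value convention — the source formula writes "log" without a base; the
base only rescales t-statistics, not p-values). The unpaired Bis −
OxBis contrast uses empirical-Bayes variance moderation: per-probe
residual variances s² (d degrees of freedom) are squeezed towards a
prior (d0, s0²) fitted by matching the mean and excess variance of
log s² with digamma/trigamma moments (trigamma inverted by Newton
iteration). The moderated t has d0 + d degrees of freedom; p-values are
BH-adjusted by default (raw optional), and a probe is called
hydroxymethylated when adjusted p < 0.05 and mean beta_Bis − mean
beta_OxBis > 0. On a fixed 30 × 4 test matrix the implementation
reproduces Bioconductor limma's d0, s0² and per-probe t/p to eight
significant digits. All-zero residual variances fall back to an
infinitely concentrated prior at the mean variance. No trend or robust
variants are implemented.

## Feature enrichment

Level bins are left-closed right-open ((0–10, 10–20, 20–30, >30)% by
default, the last unbounded); the printed bin labels overlap, so the
boundary convention is ours. Enrichment is CpG-level: expected count =
|set| × (feature CpGs / universe), O/E = observed/expected, with
hypergeometric upper-tail p for enrichment and lower-tail for depletion.
The 5hmC contribution statistic sets non-significant CpGs' 5hmC to zero
and divides region-average 5hmC by region-average 5modC (p_Bis).
Platform overlap classes (both / wg_only / array_only / neither)
partition the comparison universe; the per-region maximum WG 5hmC of
"array_only" vs "both" regions is compared by Kruskal–Wallis.

## hMeDIP testing and audit

Fragments are extended to 300 bp from their 5′ end and counted on every
overlapping 300-bp tile; tiles with < 20 total reads across samples are
dropped. The enrichment test conditions on the tile total after
mean-scaling counts to the geometric-mean library size (no normalisation
factors, per the analysis recipe): with n replicates per group and fixed
dispersion φ, the group sum is NB with size n/φ, and
P(S_IP = k | total) ∝ C(k + r1 − 1, k) C(s − k + r2 − 1, s − k).
Two-sided p-values double the smaller tail (capped at 1). Binomial-
coefficient logs are accumulated as cumulative sums of log((r + j)/(j + 1)),
which stays exact even for the enormous sizes of the Poisson limit; at
φ = 1e−8 the test agrees with the conditional binomial exact test to
< 1e−7 on all totals ≤ 50. This is an independent reimplementation of
the standard exact NB test, not a port: the quantile-adjustment scheme
of the reference package is replaced by mean-scaling with rounding, so
p-values agree closely but not identically with it. logFC/logCPM use a
0.5 prior count. Tiles with FDR < 0.1 and logFC > 0 are called enriched;
the low/medium/high logFC split uses 1.8 and 2.4 cut-offs with
boundaries in the lower bin. IP replicates are summed before the
contrast (testing replicates separately is possible by calling the test
per column).

Summit windows are summit ± 150 bp (301 bp), merged when overlapping and
clipped at chromosome ends; gaps are the complement, so windows and gaps
tile the covered genome disjointly. The permutation null shuffles the
(length, label) sequence of segments within each chromosome and re-lays
them end to end — lengths and the label multiset are preserved — then
recomputes mean(window 5hmC) − mean(gap 5hmC);
p = (1 + #{null ≥ observed})/(n_perm + 1). The source describes only "a
random permutation of summits and gaps"; the length-preserving
construction is our interpretation, chosen to control length
confounding. One caveat, found by simulation: the audit's p-value is
exactly uniform under the null only when the 5hmC landscape is spatially
exchangeable at the segment scale. With a strongly blocky landscape,
shuffled layouts can place windows adjacently (sampling autocorrelated
CpGs) while the observed layout alternates strictly, giving the null
slightly heavier tails and mid-range p-values — a conservative, not
anticonservative, distortion for the planted-signal direction tested.

Peak specificity analysis restricts to peaks whose every CpG has ≥ 10×
in both treatments, computes peak-average 5hmC under the discard/impute
rules, reports the fraction with average > 0, and compares it to
length-preserving uniform random placements of the same peaks.

## Spike-in estimators

Counts are pooled across sites within a control before ratio estimation.
With retained fractions f(assay, state):

- conversion efficiency = converted fraction at unmodified sites (1 −
  non-conversion rate), with a Wilson CI;
- 5hmC oxidation efficiency = converted fraction in OxBis at 5hmC sites
  ÷ retained fraction in Bis at the same sites, clipped to [0, 1];
- TET oxidation efficiency = 1 − f(TAB, 5mC)/f(Bis, 5mC);
- BGT protection efficiency = f(TAB, 5hmC)/f(Bis, 5hmC), capped at 1.

All four are consistent (error shrinks with depth) and recover the
generator's chemistry within 3 binomial SE at 10⁵ pooled depth. The
recovery experiments set `e_overconv = 0` so the normalising Bis
fractions are exactly 1 and the estimand equals the nominal parameter.

## Single-molecule patterns

Per read, the modified fraction of CpGs falls in one of five classes:
exactly 0, (0, 10], (10, 50], (50, 80], (80, 100]% — zero is its own
class and the remaining bins are right-closed (the printed labels
overlap, forcing a convention). All-or-none simulations concentrate mass
in the extreme classes; independent sampling at marginal 0.5
concentrates it centrally.

## Problem sizes and numerics

The test suite and acceptance script run the callers at 10⁴ CpGs
(5 × 10⁴ for the type-I error sweep), the tile test at ~10⁴ tiles, the
permutation audits at 999 permutations (199 × 50 seeds for the
uniformity check), and spike-ins at 10⁵ pooled depth — sizes chosen so
every Monte-Carlo assertion has comfortable margin while the whole suite
completes in well under a minute. Degenerate inputs are handled
explicitly: zero-coverage CpGs are the caller's error case, degenerate
2×2 margins give p = 1, all-identical Kruskal–Wallis inputs give p = 1,
zero tile totals give p = 1, and empty regions are flagged undefined
rather than averaged.
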