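# Methods

## Model

A sample's pooled per-coccolith mean-thickness values `x_1..x_N` (µm,
from circular-polariser retardation light microscopy) are modelled as a
`K`-component normal mixture, one component per morphotype present in
the sample's SEM counts:

    x_i | z_i = k ~ Normal(mu_k, 1/tau_k)
    mu_k          ~ Normal(m_0k, 1/p_0)
    tau_k         ~ Gamma(a_0, rate b_0)       (independent per component)
    g_k           ~ Gamma(alpha_k, scale 1),   g_k := max(g_k, 0.01)
    pi            = g / sum(g)                 (normalised-gamma Dirichlet)

Standard deviations are derived per draw as `sigma = 1/sqrt(tau)`.
The Dirichlet hyperpriors `alpha_k` are the SEM morphotype counts for
field samples (so the weight prior carries the observed relative
abundances with their actual count strength), and fixed design values
for the validation study. The gamma floor of 0.01 prevents zero weights
in the four-component models. Rare morphotypes (< 1% relative
abundance) are dropped before fitting, and thickness outliers are
removed in a single pass with the two-sided Tukey fence
(`[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`, quartiles by linear interpolation —
the common "type 7" rule).

Sampling is plain Gibbs: the assignments `z` from their categorical
full conditional, then conjugate updates of `mu_k`, `tau_k` and `g_k`
(`Gamma(alpha_k + n_k, 1)`, floored, then normalised). For `K >= 3` the
state is relabelled after every sweep so that component `j` is the
`j`-th thinnest (ties broken by ascending sigma), which attaches
`alpha_j` to the `j`-th thickness rank; this in-state relabelling — not
merely sorting the stored draws — is what prevents label switching from
blurring the component summaries. Two-component fits are left unsorted,
so their two slots are exchangeable up to the `alpha` asymmetry and
permuting `alpha` only relabels the fit.

Point estimates are posterior medians of the pooled post-burn-in,
thinned draws across chains; uncertainty is the central 68% credible
interval (16th–84th percentiles), roughly a one-standard-deviation
margin of error. Sigma summaries are quantiles of the per-draw
transform, never transforms of summarised precision. Convergence is
checked with the split Gelman–Rubin statistic (`R-hat < 1.1` for every
reported `mu` and `sigma`); the CLI refuses to report a non-converged
sample without an explicit override.

## Prior choices (and why they matter here)

The mixture components in these samples overlap heavily — component
means are typically one to two within-component standard deviations
apart — so the likelihood alone identifies them only weakly. Fully
vague priors admit two degenerate solutions that dominate the posterior
in that regime: a minority component can inflate its variance and
absorb the whole sample, or several components can collapse onto the
pooled centre. The defaults below are scale-adaptive, weakly
informative choices that rule those out while remaining configurable
(`MixtureConfig`):

* **Mean-prior locations `m_0k`.** For mean-sorted fits (`K >= 3`),
  rank `j` is anchored at the pooled-data quantile of the midpoint of
  its cumulative-abundance segment — where the component mean would sit
  if the components were fully separated — shrunk halfway toward the
  weighted anchor centre, the midpoint between the fully-separated and
  single-component limits. Unsorted two-component fits use one common
  location, the sample mean, preserving slot exchangeability.
* **Mean-prior precision `p_0`.** `1 / pooled variance`: a prior
  standard deviation equal to the sample's spread — informative about
  the scale, weak about the location within the data range.
* **Precision prior.** `Gamma(2, rate 2 * v_w)` where `v_w` is the
  abundance-implied within-component variance: the pooled variance
  minus the between-anchor variance (floored at a quarter of the pooled
  variance). Component spreads are therefore a priori of the order of
  the within-morphotype spread, which penalises the absorb-the-sample
  solution; the loose shape (coefficient of variation `1/sqrt 2`) lets
  the data move sigma freely within that order of magnitude.

Chains initialise at the centres of a deterministic one-dimensional
k-means pass, with clusters assigned to components so cluster sizes
best match the prior abundances (brute force over permutations,
`K <= 4`), plus per-chain Gaussian jitter of half the pooled spread.
This keeps initialisation covariant under permutations of `alpha` and
prevents a high-count component from freezing onto the wrong side of a
well-separated sample.

## Iteration schedules

Two shipped profiles:

| profile | iterations | burn-in | thinning | chains |
|---------|-----------:|--------:|---------:|-------:|
| `paper` | 500 000 | 50 000 | 100 | 3 |
| `desk`  | 50 000 | 5 000 | 10 | 3 |

The desk profile is used by the test suite and the acceptance script;
on the sample sizes handled here its posterior summaries agree with the
long schedule to well within the credible intervals (checked directly:
the two schedules give medians identical to three decimals on the
validation designs). All randomness flows through a single seed; runs
are bit-reproducible on a given platform.

## Synthetic data

`table2_scenarios()` reproduces the eight-group validation design:
twelve two-component samples (N = 200; abundance splits 25/75 and
10/90; means 0.100/0.120 µm, or both 0.110 µm in the equal-mean
groups) and four four-component samples (N = 500; means spanning
0.085–0.125 or 0.080–0.140 µm; one design with matching hyperpriors,
two with permuted abundances, probing input-order robustness). The
designed SD of 0.020 describes the *pooled* sample distribution; the
common per-component SD is derived by removing the between-mean
variance (`Scenario.from_sample_sd`), giving 0.020 in the equal-mean
groups down to 0.0084 in the widest four-component design. Draws are
plain normals (no truncation at zero; at these means negative draws
are vanishingly rare).

`simulate_field_sample` generates matched SEM + LM tables with the
correlation structure the analysis assumes: morphotype by the spec
proportions; normal lengths; widths tied to length by a fixed aspect
ratio; normal per-morphotype thickness; LM mass equal to the volumetric
model times multiplicative noise (default CV 0.14, the order of the
light-microscope mass uncertainty); central-tube widths for Type A
only; only the overcalcified morphotype flagged as LM-distinguishable.
It does not emulate instrument artefacts, within-morphotype
subvarieties, length–thickness correlation, or non-normal tails — so
passing recovery tests demonstrate the estimator works when its
assumptions hold, not that field samples satisfy them.

## Validation study and its honest limits

`run_simulation_study` regenerates the sixteen samples from a master
seed (per-sample data and fit seeds split from one generator stream),
fits each with the design hyperpriors (`alpha = (20, 80)` for every
two-component model, `(10, 35, 35, 20)` for every four-component
model), and scores each of the forty components by the absolute error
of the posterior-median mean and by whether the true mean falls in the
68% interval. Estimated components are matched to true components by
thickness rank, since the slot labels of unsorted two-component fits
freeze arbitrarily during burn-in. Up to two worst components *from
the equal-mean designs only* may be excluded from the headline maximum
error, mirroring the two known failures of this design family.

Measured behaviour at the desk schedule (master seeds 1–3): the
four-component designs recover all means to within about ±0.01 µm,
including the permuted-abundance designs; the separated two-component
designs recover the majority component well but the minority component
(one pooled SD below the bulk, 20–50 data points) carries errors up to
about 0.02 µm; the equal-mean designs cluster at the common mean with
occasional larger excursions. The headline maximum error is therefore
typically 0.016–0.019 µm rather than 0.01 µm, and 68%-interval
coverage is 68–72% — i.e. the intervals are calibrated in the ordinary
Bayesian sense rather than conservative. Direct checks (EM fits,
profile likelihoods, and very long chains on the same draws) show the
two-component minority limit is a property of the data: at N = 200 and
one-SD separation the likelihood often prefers mirrored or merged
configurations, and no estimator using only the pooled distribution
plus count priors resolves it uniformly. These limits are inherent to
regenerated draws under the stated design and are reported as measured.

## Morphometry

Mass uses the elliptical-slab model `m = pi (l/2)(w/2) t d` with
calcite density 2.71 g/cm³; with lengths in µm the product is directly
in pg. Calcite concentration is `CD * m * N_cocco * 1e-6` µg/L, with
`N_cocco` in {10, 23, 48} (literature minimum / mean / maximum),
assumed morphotype-independent. The central-tube ratio averages the two
per-side widths before dividing by length; the aspect ratio is
length/width and is at least 1 under the axis convention. Computations
carry full precision; comparisons against printed tables round to the
table's precision.

## Group statistics

Mann–Whitney U (exact for small tie-free inputs, otherwise
tie-corrected normal approximation with continuity correction, flagged
via `exact_p`), tie-corrected Kruskal–Wallis with chi-square p-values,
Welch's t (unequal variances — the safer default since equal variances
were not assumed), and Shapiro–Wilk normality tests. All two-sided; no
multiple-testing correction is applied, matching the descriptive use.

## Degenerate inputs and failure flags

Fewer than four thickness values cannot define the outlier fence and
raise; `k` larger than the number of distinct data values raises; a
non-finite sampler state raises with the iteration index. Empty
components fall back to their priors (precision floored at the smallest
positive double). Fits where component-mean draws fall below the
smallest measured value — the known symptom of a mis-specified
component count, seen in sparse field samples — are flagged in the
results object (`frac_mu_below_data_min`) and in `summary()`, never
hidden.
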