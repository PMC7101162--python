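# coccomix

Morphotype-resolved coccolith thickness, mass and calcite budgets for
*Emiliania huxleyi* by Bayesian mixture deconvolution.

## The problem

*E. huxleyi*, the most abundant coccolithophore in the modern ocean,
occurs as several coccolith morphotypes (Type A, "Overcalcified" Type A,
Group B, malformed) that differ in calcification. Polarised light
microscopy (the circular-polariser retardation technique) measures the
thickness and mass of individual coccoliths but — with the exception of
the overcalcified form — cannot tell the morphotypes apart; scanning
electron microscopy identifies and counts morphotypes but does not give
thickness. `coccomix` joins the two: the pooled light-microscope
thickness distribution of a sample is modelled as a finite mixture of
normals, one component per morphotype, whose mixture-weight prior is
informed by the SEM counts:

    x_i | z_i = k  ~  N(mu_k, 1/tau_k)
    mu_k           ~  N(m_0k, 1/p_0)
    tau_k          ~  Gamma(a_0, b_0)           sigma_k = 1/sqrt(tau_k)
    g_k ~ Gamma(alpha_k, 1),  g_k := max(g_k, 0.01),  pi = g / sum(g)

with `alpha` the SEM morphotype counts (a Dirichlet prior on the
weights via the normalised-gamma construction). A Gibbs sampler draws
the posterior; for three or more components the state is relabelled
every sweep so component *j* is the *j*-th thinnest (label-switching
control). Point estimates are posterior medians with 68% credible
intervals (16th–84th percentiles), roughly a one-standard-deviation
margin of error; convergence is monitored with the split Gelman–Rubin
statistic over three chains.

Posterior thickness then feeds two closed forms: per-morphotype
coccolith mass from the elliptical-slab volumetric model

    m = pi * (l/2) * (w/2) * t * d          [pg]  (d = 2.71 g/cm^3)

and population calcite concentration

    Ca = CD * m * N_cocco * 1e-6            [ug/L]

with cell density `CD` (cells/L) and 10 / 23 / 48 coccoliths per cell
as a plausible range. The package is aimed at coccolithophore
ecologists and palaeoceanographers working with paired SEM and
birefringence measurement tables.

## Worked example

Generate a synthetic winter-coastal sample (77% Type A at 0.131 µm
mean thickness, 23% Group B at 0.097 µm, 300 coccoliths, 41 003
cells/L) and run the full per-sample analysis:

```python
from coccomix import MixtureConfig
from coccomix.synthetic import (FieldSampleSpec, MorphotypeSpec,
                                simulate_field_sample)
from coccomix.pipeline import fit_sample

spec = FieldSampleSpec(
    sample_id="winter-coastal",
    morphotypes={
        "A": MorphotypeSpec(0.77, 3.36, 0.30, 1.21, 0.131, 0.020),
        "B": MorphotypeSpec(0.23, 3.18, 0.35, 1.20, 0.097, 0.018),
    },
    n_coccoliths=300, cell_density=41003.0,
)
sem, lm, meta = simulate_field_sample(spec, seed=42)
fit = fit_sample("winter-coastal", sem, lm, meta,
                 mixture=MixtureConfig.desk(), seed=7)
print(fit.results.summary())
print(fit.mass_table.round(3))
print({k: round(v, 2) for k, v in fit.calcite.items()})
```

prints

```
Count-informed normal mixture (Gibbs)
  n = 295, k = 2, chains = 3, retained draws/chain = 4500
  alpha = (230.0, 70.0), sorted means = False
  68% credible intervals (central percentiles of pooled draws)

  component       mu_lo   mu_med    mu_hi   sig_lo  sig_med   sig_hi  rhat_mu
  A              0.1215   0.1310   0.1329   0.0170   0.0184   0.0225    1.016
  B              0.0915   0.0955   0.1311   0.0128   0.0150   0.0180    1.016

            length_um  width_um  thickness_um  mass_pg  estimable
morphotype
A               3.374     2.789         0.131    2.623       True
B               3.139     2.616         0.095    1.668       True

{10: 0.99, 23: 2.27, 48: 4.74}
```

Five of 300 thickness values were removed as Tukey outliers (n = 295).
The deconvolved medians recover the generating means (A: 0.131 µm
vs true 0.131; B: 0.096 vs 0.097) even though the two morphotypes are
indistinguishable in the pooled histogram; the mass table combines the
SEM mean lengths/widths with the posterior thickness (Type A 2.6 pg,
Group B 1.7 pg), and the final line is the population calcite
concentration (µg/L) under 10 / 23 / 48 coccoliths per cell.

The same workflow is available from the shell:

```bash
coccomix fit --sem sem.csv --lm lm.csv --meta meta.csv \
             --profile desk --seed 7 --out-dir results/
coccomix simulate --table2 --seed 1 --out-dir fixtures/
coccomix evaluate --seed 1 --out-dir report/
```

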