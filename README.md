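# isodiet

Stable-isotope diet analysis for marine consumers, built around the
giant manta ray (*Manta birostris*) case study: how much of a hard-to-
observe planktivore's diet comes from surface zooplankton, and how much
from mesopelagic (deep, 200–1000 m) prey?

Bulk δ13C and δ15N of muscle tissue record what an animal assimilated
over months. `isodiet` implements the full analysis chain used to turn
such measurements into diet estimates:

- **δ-notation arithmetic** — δᴴX (‰) = (R_sample/R_standard − 1) × 1000.
- **Lipid normalization** of δ13C driven by the tissue C:N ratio,
  δ13C_LN = δ13C_bulk + 7.95 (C:N − 3.8)/C:N, applied *per sample* and
  triggered only when a group's mean C:N exceeds 3.5.
- **Trophic position**, T_L = (δ15N_consumer − δ15N_base)/Δ15N + 2.5,
  for configurable baselines and diet–tissue discrimination factors
  (DTDFs).
- **A Bayesian mass-balance mixing model**: for isotope *j*,
  y_ij ~ N( Σ_k p_k (μ_kj + c_kj), Σ_k p_k² (ω_kj² + τ_kj²) + ε_j² ),
  with diet proportions **p** on the simplex under a Dirichlet(1) prior,
  sampled by adaptive random-walk Metropolis on an additive-log-ratio
  reparameterization, with R̂ / effective-sample-size diagnostics. A
  four-model batch crosses two zooplankton treatments (bulk vs
  lipid-normalized) with two elasmobranch DTDF sets and averages the
  per-model posterior means.
- **Isotopic-niche ellipses**: standard ellipse area SEA = π√det(S),
  small-sample SEAc, a closed-form Bayesian SEA posterior
  (normal–inverse-Wishart), and numeric ellipse–ellipse overlap.
- **Cohort statistics**: two-way ANOVA (sequential SS) and Tukey HSD.
- **Synthetic-data generators** for every input, so the whole pipeline
  is testable without any field data.

## Worked example

Reconstitute 75 consumers from the published muscle-tissue moments
(δ13C −16.8 ± 1.1 ‰, δ15N 10.6 ± 1.5 ‰) and run the four-model suite:

```python
from isodiet import (SourceSpec, DiscriminationFactor, MCMCSettings,
                     consumers_from_moments, run_model_suite, average_models)

consumers = consumers_from_moments(-16.8, 1.1, 10.6, 1.5, 75, seed=1,
                                   species="Manta birostris", match_moments=True)
meso = SourceSpec("mesopelagic sources", -17.6, 0.8, 6.2, 1.5)
sources = {
    "lipid_normalized": [SourceSpec("surface zooplankton", -19.7, 1.0, 7.8, 1.0), meso],
    "bulk": [SourceSpec("surface zooplankton", -20.5, 0.6, 7.8, 1.0), meso],
}
dtdfs = {
    "large_shark": DiscriminationFactor(0.9, 0.33, 2.29, 0.22, "large_shark"),
    "leopard_shark": DiscriminationFactor(1.7, 0.5, 3.7, 0.4, "leopard_shark"),
}
summaries = run_model_suite(consumers, sources, dtdfs, mcmc=MCMCSettings(seed=1))
for s in summaries:
    print(f"{s.label}: surface {s.means[0]:.2f} +/- {s.sds[0]:.2f}, "
          f"mesopelagic {s.means[1]:.2f} +/- {s.sds[1]:.2f} "
          f"(converged={s.converged})")
for name, (m, sd) in average_models(summaries).items():
    print(f"average {name}: {m:.2f} +/- {sd:.2f}")
```

which prints

```
Model 1: surface 0.21 +/- 0.07, mesopelagic 0.79 +/- 0.07 (converged=True)
Model 2: surface 0.11 +/- 0.05, mesopelagic 0.89 +/- 0.05 (converged=True)
Model 3: surface 0.43 +/- 0.05, mesopelagic 0.57 +/- 0.05 (converged=True)
Model 4: surface 0.32 +/- 0.04, mesopelagic 0.68 +/- 0.04 (converged=True)
average surface zooplankton: 0.27 +/- 0.14
average mesopelagic sources: 0.73 +/- 0.14
```

Every model attributes the majority of the diet to mesopelagic sources;
averaged across the four configurations the split is 27% surface
zooplankton / 73% mesopelagic. Model 3 (lipid-normalized zooplankton,
leopard-shark DTDF) is the most favourable to surface feeding and still
reaches only 43%.

## Command line

```bash
isodiet simulate --out-dir syn --seed 1        # synthetic consumers + tows
isodiet normalize --input syn/tows.csv --out ln.csv
isodiet trophic --input syn/consumers.csv
isodiet mix --input syn/consumers.csv --out mixing.csv
isodiet all --input samples.csv --out-dir results   # full pipeline + manifest
```

`isodiet all` writes Table-1-style group summaries, trophic positions,
the four mixing posteriors with the model average, ellipse and overlap
tables, ANOVA/Tukey tables, and a `manifest.json` with the seed, config
echo, convergence diagnostics and a SHA-256 digest of every report.
Reruns with the same seed are byte-identical.

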