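# scnkit

Simulation and pixel-level analysis of circadian rhythms in the
suprachiasmatic nucleus (SCN), built around two ideas:

1. **A stochastic amplitude–phase oscillator network with dual neuropeptide
   coupling.** Each neuron is a noisy limit-cycle ("Poincaré") oscillator

   ```
   dx_i/dt = −λ_i x_i r_i (r_i − α_i) − ω_i y_i
             + Σ_{j∈N_i} K (x_j − x_i)
             + I_avp sin(2πt/24) + I_vip sin(2π(t+φ)/24) + ξ_x,i
   dy_i/dt = −λ_i y_i r_i (r_i − α_i) + ω_i x_i + ξ_y,i
   ```

   with r_i = √(x_i²+y_i²). The diffusive coupling is decomposed into the
   two major SCN coupling channels, `K = a_avp·K_avp + a_vip·K_vip`, whose
   attenuation factors encode genotype and age (development attenuates VIP;
   Cry1/2 knockout attenuates AVP; the additional Vipr2 knockout removes VIP
   entirely). Co-culture with a rhythmic wild-type graft is a pair of 24-h
   sinusoidal forcings whose relative phase delay φ decides whether the two
   channels cooperate (φ = 0 h) or compete (φ ≈ 11–12 h) — the mechanism by
   which *blocking* AVP signalling can paradoxically *improve* a rescued
   rhythm.

2. **Empirical orthogonal functions (EOFs) for bioluminescence movies.** A
   PER2::LUC movie is a T×N matrix A (one column per pixel); the EOFs are
   the eigenvectors e_i of the pixel covariance matrix R = AᵀA, the
   normalized eigenvalues `100·Ω_i/ΣΩ_j [%]` quantify how much variance
   each spatial pattern carries, and the projections c_i(t) are the
   temporal modes. A synchronized slice concentrates ~80–95 % of variance
   on the first mode; desynchronized tissue spreads it below 5 % per mode.

Because real slice recordings are rarely shareable, the package includes a
synthetic imaging model (baseline decay, photon noise, several pixels per
cell) so that every analysis stage is testable end to end, plus rhythm
metrics used alongside the EOFs: the Sokolove–Bushell chi-square
periodogram, cosine-fit acrophase, the Kuramoto synchronization index R,
the 24-h Fourier-component ratio for drug treatments, and one-way ANOVA
with Fisher's LSD for slice-group comparisons.

It is intended for chronobiologists and modellers who want to explore how
dual coupling shapes spatio-temporal SCN patterns, and as a reference
implementation of EOF-based rhythm quantification.

## Worked example

Simulate a neonatal wild-type slice (two 120-cell lobes, 6 days, hourly
frames), render it through the imaging model and summarize:

```python
from scnkit import (scenario_preset, simulate_network, render_movie,
                    ImagingModel, preprocess, compute_eof, summarize_slice)

run = simulate_network(scenario_preset("neonate-wt", seed=1))
movie = render_movie(run, ImagingModel(), seed=2)

summary = summarize_slice(movie)
print(f"period: {summary.period_mean:.2f} +/- {summary.period_sd:.2f} h "
      f"({summary.n_rhythmic} rhythmic pixels)")
print(f"first+second EOF variance: {summary.eig12_sum:.1f} %")
print(f"synchronization index R: {summary.sync_mean:.3f} +/- {summary.sync_sd:.3f}")

eof = compute_eof(preprocess(movie))
print("leading eigenvalue shares [%]:", [round(v, 1) for v in eof.normalized[:4]])
```

prints

```
period: 23.74 +/- 0.26 h (960 rhythmic pixels)
first+second EOF variance: 95.6 %
synchronization index R: 0.909 +/- 0.014
leading eigenvalue shares [%]: [84.9, 10.7, 0.7, 0.5]
```

— a fully synchronized slice: every pixel is rhythmic near 24 h, the first
mode carries ~85 % of the variance and the second (~11 %) picks up the
phase-advanced dorsomedial cells, which are assigned shorter intrinsic
periods in this preset.

The same pipeline from a shell:

```bash
scnkit simulate --preset coculture-tko --seed 7 --out demo/
scnkit analyze --movie demo/movie.csv --coords demo/coords.csv --out demo_report/
```

`demo_report/summary.json` for this rescued triple-knockout co-culture
shows the partial rescue by AVP forcing: `eig12_sum ≈ 30 %`,
`period_mean ≈ 24.0 h`, `sync_mean ≈ 0.49` — compare
`--preset coculture-tko-antagonist`, where blocking AVP receptors removes
the only remaining input and every eigenvalue drops below 5 %.

Other presets: `neonate-wt`, `neonate-dko`, `neonate-dko-split` (the
left/right "splitting" regime with 21 h vs 32 h lobes), `neonate-tko`,
`adult-wt`, `adult-dko`, `adult-tko`, `coculture-dko`,
`coculture-dko-antagonist`, `coculture-tko`, `coculture-tko-antagonist`.
The CLI also provides `estimate` (single-cell parameter fitting by
autocorrelation, with the CV < 1 self-sustained / CV > 1 damped
classification), `sweep` (synchronization diagrams over coupling or
forcing parameters), `report` (ANOVA + LSD across slice groups) and
`make-fixture`.

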