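# Methods

## The single-cell model

Each cell is a stochastic limit-cycle oscillator in Cartesian coordinates,

    dx/dt = −λ x r (r − α) − ω y + ξ_x
    dy/dt = −λ y r (r − α) + ω x + ξ_y ,      r = √(x² + y²).

The deterministic part has a circular attractor of radius α and angular
frequency ω; off-cycle perturbations relax at rate γ = λα (linearized about
r = α). Noise is parameterized in the local co-rotating frame: a radial
intensity D_r (signal units²/h) and a phase intensity D_φ (rad²/h). In the
integrator the radius receives the displacement √(2·D_r)·dW along the radial
unit vector and the phase an exact rotation by √(2·D_φ)·dW′, so the radial
coordinate follows the one-dimensional SDE dr = −λr(r−α)dt + √(2·D_r)dW
exactly and the phase is a Brownian motion with diffusion D_φ superimposed
on the ω-rotation. This construction keeps both noise channels individually
interpretable and individually testable (the test-suite checks the radial
stationary variance against an independent 1-D integration and the ensemble
phase variance against the 2·D_φ·t law).

### Integration

Euler–Maruyama with operator splitting, default dt = 0.01 h for single
cells and 0.05 h for networks, sampled hourly to mimic 60-min imaging: per
step (i) Euler for additive terms (coupling, forcing) in x, (ii) Euler for
the radial relaxation, (iii) exact rotation by ω·dt, (iv) the local-frame
noise. On the noise-free cycle the radius is conserved to machine precision
and the period is exact; the forced coherent response is step-size
consistent across dt ∈ {0.05, 0.01, 0.005}. A step-size guard requires
dt·max(λα, ω) < 0.1; radial over-relaxation (a state so far off the
attractor that one Euler step would overshoot the origin) and any
|x| > 10³·α raise an integration-failure error naming the step. One root
seed spawns independent sub-streams for geometry, period assignment,
initial phases and dynamics noise, so every run is exactly reproducible.

### The CV criterion

The coefficient of variation of the amplitude classifies cells:
CV < 1 ⇒ self-sustained oscillator, CV ≥ 1 ⇒ noisy damped oscillator. On
the parameter side (`compute_cv`) we use the Ornstein–Uhlenbeck stationary
s.d. of the linearized radial dynamics, CV = √(D_r/(λα))/α, taking λα as
the relaxation rate (the linearization of dr/dt = −λr(r−α) about r = α; a
plain-λ convention would only rescale the same quantity by √α and is easy
to substitute).

On the data side (`AmplitudePhaseFitter`) the parameters are estimated by
fitting the model autocorrelation function to the empirical (biased) ACF of
the detrended trace. Under the independence of radial and phase
fluctuations the model ACF factorizes exactly:

    ρ(τ) = (α² + σ_r² e^{−γτ}) / (α² + σ_r²) · e^{−D_φ τ} · cos(ωτ),

which identifies four shape parameters {ω, γ, D_φ, CV² = σ_r²/α²}; the
amplitude scale comes from the trace variance Var(x) = (α² + σ_r²)/2. The
expected finite-window taper (1 − τ/T) of the biased estimator is applied
to the model before comparison. Fitting is bounded least squares with five
multi-start restarts (ties broken by residual, then by lower CV); a
non-converged fit is flagged but the best attempt is still returned. A
simulation-averaged model ACF (`model_acf(..., method="simulation")`) is
available as a slower alternative that avoids the analytic factorization.

Two deliberate conventions:

* **No separate measurement-noise term.** Photon noise in a measured trace
  is absorbed into CV², i.e. CV measures the *incoherent share* of the
  recorded variance whatever its source. This is what makes the criterion
  operational on real dispersed-cell data: a cell whose rhythm carries less
  than half the recorded variance is "damped". A consequence is that the
  damped regime is reproducible only on traces rendered through the imaging
  model (intrinsic amplitude noise alone cannot push the incoherent share
  of this model class much above 50 %).
* **γ is floored at 0.15/h.** Over a 72-h lag window a slow amplitude decay
  is nearly degenerate with phase diffusion, and letting γ roam made the
  CV estimate unstable (identical data fit anywhere between 0 and 2.6).
  With the floor, slow envelope decay is attributed to D_φ and the CV
  captures the fast incoherent variance robustly; γ and λ should therefore
  be read as nuisance shape parameters, while period and CV are the
  recovered quantities (period recovered within ~3 % for sturdy
  oscillators; CV-label accuracy 80–100 % across a grid spanning CV
  0.2–2.0).

## The network model

Cells sit on two disc-shaped 4-neighbour lattices (default 120 cells per
lobe ⇒ 240 cells) joined by a small number of weak "bridge" edges (default
4 edges at 10 % of intra-lobe weight); the topology is not observable in
movie data, so the lattice is the simplest local-coupling choice and every
aspect of it is configuration. The innermost-dorsal 10 % of each lobe is
labelled dorsomedial and can receive a period offset (−1 h in the wild-type
preset, reproducing the phase-advanced dorsomedial cluster that the second
EOF mode picks up). Intrinsic periods are Gaussian per cell: 24 ± 1.5 h for
wild-type fits, 24 ± 5 h for knockout fits (rescued knockout slices show
periods spanning roughly 15–37 h, which a narrow spread cannot produce).

Initial phases are drawn with s.d. 0.5 rad about a common phase: slices
come out of a light-entrained animal, so the tissue starts phase-ordered.
Weakly coupled scenarios disperse during the 48-h discarded transient
through phase diffusion and period heterogeneity; this matters because a
locally coupled lattice started from uniformly random phases would need
far longer than any 6-day recording to synchronize globally, which is not
what slice recordings show.

### Parameter choices

The two single-cell fits and the coupling scale are free constants of the
model (they are only identifiable jointly with the imaging model); they
were selected once, from synchronization-diagram-style scans, to place each
experimental condition in its observed dynamical regime, and are not
adjusted per experiment:

| quantity | wild-type fit | knockout (Cry1/2⁻) fit |
|---|---|---|
| α (amplitude) | 1.0 | 0.01 |
| λ (1/h) | 0.05 | 60 |
| γ = λα (1/h) | 0.05 | 0.6 |
| D_r | 4.5·10⁻³ | 1.2·10⁻⁴ |
| D_φ (rad²/h) | 0.005 | 0.06 |
| CV (linearized) | 0.30 | 1.41 |

K_vip = K_avp = 0.05 per edge, so the total per-edge coupling
K = a_avp·K_avp + a_vip·K_vip spans [0, 0.1]. Attenuation presets:
wild-type neonate a_vip = a_avp = 1; adult wild-type a_vip = 0.3 (VIP
signalling attenuates through development); all double-knockout presets
a_vip = a_avp = 0.1 (AVP expression is strongly reduced without Cry1/2;
this 0.1/0.1 operating point is also the one used for the co-culture
forcing experiments); triple-knockout presets a_vip = 0 with the VIP
receptor absent, which also makes external VIP forcing ineffective even
though a co-cultured graft still secretes it. Co-culture forcing uses
I_vip = I_avp = 0.01 with phase delay φ = 11 h (antagonistic regime);
AVP-antagonist treatment sets I_avp = 0 and, because the blockade acts on
recipient cells too, a_avp = 0 (switchable).

With these values the model reproduces, without per-case tuning: a
synchronized wild-type slice (first mode ≈ 82 %, second mode ≈ 10 %
dorsomedial), desynchronized knockouts (all modes ≤ 5–10 %), the co-culture
rescue of the triple knockout by AVP forcing alone (first mode ≈ 29 %,
period mode 24 h), the loss of that rescue under AVP antagonists (< 5 %),
the paradoxical improvement of the double-knockout rescue by antagonists
(two nearly antiphase forcings cancel; removing one quadruples the net
drive), and R(φ=0) > R(φ=12) in the forcing-phase sweep.

The splitting preset (`neonate-dko-split`) models the minority of neonatal
double-knockout slices in which the two lobes lock internally but run at
distinct periods (~21 h vs ~32 h, right-lobe offset +11 h, period s.d.
0.5 h, two bridges). It uses its own cell fit (α = 0.5, γ = 0.05,
CV = 0.5, D_φ = 0.005) — the rhythmic tail of the knockout CV
distribution — because with the noise-dominated knockout fit diffusive
coupling suppresses the tiny oscillations ("amplitude-death"-like) instead
of locking them at any attenuation ≤ 1, and because a lobe-period
difference much smaller than ~10 h cannot decorrelate the lobes within a
6-day record (a +3 h offset gives only 0.67 relative cycles in 144 h). The
lobe purity of the two leading modes is 1.00 across tested seeds.

## Synthetic imaging

`render_movie` maps oscillator states to camera counts:

    pixel(t) = baseline · e^{−t/τ} · max(1 + gain·x(t), 0) + noise,

with baseline 4·10⁴ counts (hour-long EMCCD exposures of tissue), culture
decay τ = 150 h, reporter modulation depth gain = 0.6, and four adjacent
pixels per cell sharing the cell's trace with independent noise (ROI ≈
100 µm² cells at ~2 µm pixels). "poisson-like" noise is Gaussian with
variance equal to the mean (the photon-counting normal approximation —
exact Poisson sampling differs negligibly at these counts); a
constant-variance "gaussian-scaled" option exists for analytic tests.
Counts are clipped at zero after adding noise, which slightly biases very
dim pixels. Dispersed single cells are rendered at baseline 5·10³ counts —
an isolated cell is much dimmer than stacked tissue — and this photon
budget is what makes measured knockout cells classify as damped, exactly as
with real dispersed recordings.

What the generator does **not** emulate: cell movement and drift, optics
(PSF blur, vignetting), spatially correlated background, segmentation
errors, and medium-change artifacts. Passing tests therefore demonstrate
correctness of the analysis chain and the qualitative physics of dual
coupling, not robustness to every nuisance of real microscopy.

## Analysis chain

* **Detrending** (`preprocess`): per pixel, subtract a least-squares
  quadratic baseline, subtract a centered 24-h moving average, divide by
  the centered moving s.d. (shrinking windows at the edges), and remove the
  residual mean. The explicit baseline step matters: shrinking edge windows
  systematically under-correct a monotone exponential decay, which
  otherwise injects a spurious common "mode" of up to ~25 % variance into
  desynchronized movies. Constant pixels are zero-filled with a warning.
* **EOF** (`compute_eof` / the sklearn-style `EOF` transformer):
  eigendecomposition of the column-centered covariance AᵀA (the dual T×T
  problem when N > T), eigenvalues descending, normalized shares summing to
  100 % by construction; verified against an SVD oracle to 10⁻⁸ and by the
  energy identity ΣΩ_i = ‖A‖²_F. An uncentered mode is available by flag;
  centering is the default so that R is a true covariance matrix.
* **Pixel classification** (`classify_pixels`): arg-max of |loading| over
  the first two modes, cut at 0.5/√N (half the r.m.s. loading of a fully
  delocalized mode); pixels below the cut stay unclassified. Period and
  acrophase histograms are reported for classified pixels.
* **Chi-square periodogram** (`period_chisq`, `periods_by_pixel`): the
  record is folded at each candidate period (grid 15–40 h, 0.1-h steps,
  capped at a third of the record) into ~dt-wide phase bins; the
  ANOVA-normalized statistic Q_P = Σ_h n_h (M_h − M)²/σ̂² is ≈ χ²(K−1)
  under white noise (measured per-candidate exceedance 0.9 % at the 1 %
  line). Because a 250-candidate scan would otherwise flag 82 % of pure
  white-noise records somewhere, the detection level is Bonferroni-divided
  across the grid by default, making "has a significant period" a
  family-wise statement; the best period is the significant candidate with
  maximal Q (selecting by excess over the significance line instead biases
  the estimate one grid step short, because the line grows with the bin
  count).
* **Acrophase**: least-squares cosine fit at the pixel's significant
  period; peak time modulo the period, mapped to [0, 24) for display.
* **Synchronization index**: R(t) = |N⁻¹ Σ_k e^{iθ_k(t)}| with
  analytic-signal (Hilbert) phases of the detrended traces, evaluated at 24
  hourly points in the final day; mean and s.d. over those points. The
  finite-N floor for random phases, E[R] ≈ √π/(2√N), is verified in tests.
* **24-h component ratio**: the Fourier coefficient nearest 1/24 h⁻¹ of the
  ensemble-mean trace, window trimmed to whole cycles to avoid leakage;
  after/before ratio > 1 means the treatment strengthened the rhythm.
* **Group statistics**: one-way ANOVA (scipy) plus Fisher's LSD post hoc
  (pooled-MSE t tests, df = N − k), flagged at p < 0.01 by default;
  single-slice groups are excluded with a warning.

## Numerical choices and degenerate inputs

Constant traces raise an explicit normalization error in the ACF; an
all-zero movie raises on decomposition; zero-amplitude cosine fits flag the
acrophase as undefined; a zero before-treatment amplitude makes the
component ratio infinite with a warning; periodogram grids coarser than the
sampling interval are rejected. All stochastic behaviour is reproducible
from a single seed.

## Problem sizes

Defaults are desk-scale by design: 240 cells (960 pixels), 144 h of hourly
samples after a 48-h transient, dt = 0.05 h for networks. One full
simulate–render–detrend–decompose pipeline takes well under a second, the
whole test-suite under two minutes, and the acceptance script (60 full
runs plus per-pixel periodograms) under a minute on one CPU. Larger
lattices and longer recordings are plain configuration changes.

## Known limitations

* The lattice topology, coupling magnitudes and single-cell noise levels
  are jointly identifiable only up to the imaging model; the defaults are a
  calibrated operating point, not measurements.
* The CV criterion is an incoherent-share estimate and saturates near ~0.7
  for noiseless traces of this model class; damped classifications assume
  photon-limited recordings.
* GABA signalling, retinal input, photoperiod effects and gene-regulatory
  detail are outside the model's scope; the amplitude–phase abstraction is
  deliberately agnostic about molecular mechanism.
* EOF modes are orthogonal by construction; when two biological patterns
  are not orthogonal (e.g. overlapping clusters), loadings mix them and the
  red/green classification inherits that mixing.
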