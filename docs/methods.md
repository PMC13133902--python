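# Methods

## Level diagram and channel energetics

All energies are in eV relative to the anion ground-state (S₀) minimum.
The diagram stores detachment thresholds — VDE(D₀), ADE(D₀), VDE(D₁ₙ) —
as `{provenance: value}` maps because the experiment and the calculation
give slightly different numbers (measured VDE 2.63 eV vs calculated
2.54 eV) and an analysis must be explicit about which it uses. Every
operation therefore takes explicit threshold values; the diagram only
provides lookup with a preferred provenance.

Closed channels (non-positive eKE) are returned as flagged values rather
than exceptions so that a simulator can iterate over a channel list
uniformly; genuinely inconsistent inputs (a binding energy larger than the
photon energy, a state above the pump photon) raise.

The spectral-region classifier maps a (hν, eKE) pixel to one of the labels
i–v or `unassigned` under a fixed priority: two-photon (iii) before the
direct ridge (i) before the excited-neutral ridge (ii) before resonant
broadening (v) before low-eKE statistical emission (iv). Two-photon
electrons are *defined* by exceeding the direct line by more than the
tolerance, so they are tested first; a ridge can only claim pixels when
its channel is open (hν above the threshold). The tolerance (default
0.1 eV), the low-eKE cutoff (default 0.1 eV), the broadening tolerance
(default 3× the ridge tolerance) and the resonance window (3.6–3.9 eV)
are all parameters.

## RRKM / QET statistical lifetime

The trapped state decays over a barrier E₀ (the lowest conical
intersection on the pathway out of the excited-state minimum; 0.41 eV for
meta-HBDI) with the microcanonical rate

    k(E) = σ · W‡(E − E₀) / (h · ρ(E)),

E being the vibrational energy above the excited-state zero-point level.
Model content and assumptions:

- **Harmonic direct count only.** W and ρ come from exact Beyer–Swinehart
  counting on a 1 cm⁻¹ grid (each frequency rounded to the nearest grid
  multiple; the count is exact for the rounded set). No anharmonicity, no
  rotational densities, no tunnelling. The transition-state set has one
  mode fewer than the minimum (the reaction coordinate).
- **Density smoothing.** The exact per-bin density is a shot-noise-like
  staircase; the rate uses ρ averaged over a 100 cm⁻¹ window snapped to
  whole bins. This makes k(E) stable to better than 1% under bin
  refinement (2 → 1 cm⁻¹) for many-mode systems at E ≥ E₀ + 0.1 eV.
  Within ~0.1 eV of the barrier, W‡ is a small integer and k(E) shows a
  physical staircase — it is not strictly monotone there, and no smoothing
  choice should hide that.
- **Thermal preparation.** The stored ions are canonical at temperature T:
  P(Eᵥ) ∝ ρ_S0(Eᵥ)·exp(−Eᵥ/k_B T), normalized on the grid; T = 0 is a
  point mass at Eᵥ = 0. The grid extends 12 standard deviations of the
  harmonic energy distribution beyond its mean, and construction fails
  loudly if the truncated tail is not negligible. Ground-state (S₀)
  frequencies are used for this pre-excitation distribution; after the
  pump, the same synthetic set stands in for the S₁ manifold in the
  convenience pipeline (callers with distinct sets can assemble the
  pieces directly).
- **Excitation mapping.** A pump photon hν promotes each member to
  internal energy E = Eᵥ + hν − AEE in the trapped state, i.e. vertical
  energy bookkeeping with complete conversion of excess energy to
  vibration.
- **Lifetime convention.** The ensemble survival
  S(t) = Σ P(Eᵥ)·exp(−k(E)·t) is non-exponential; "the lifetime" is
  defined as the 1/e crossing of S(t), found by linear interpolation in
  log S. A window that does not bracket the crossing raises with
  instructions rather than extrapolating.
- **Symmetry factor** σ defaults to 1.

Physical constants: h = 4.135667696×10⁻¹⁵ eV·s,
k_B = 8.617333×10⁻⁵ eV/K, 1 eV = 8065.544 cm⁻¹,
hc = 1239.84193 eV·nm.

With the packaged defaults (78 modes drawn uniformly from 50–3500 cm⁻¹,
barrier 0.41 eV, 300 K, 400 nm pump, AEE 1.51 eV) the pipeline gives
lifetimes of order 10² ps. Because the true vibrational frequencies of the
molecule are not part of the inputs, the computed value is a
regime-and-trend statement (picoseconds to nanoseconds; decreasing with
temperature and photon energy), not a prediction of the specific ~10² ps
number an exact frequency set would give.

## Sequential kinetics and transient fitting

The three-state model S₂ → S₁ → S₀ has the analytic solution
P_S2 = e^{−k₁t}, P_S1 = k₁/(k₂−k₁)(e^{−k₁t} − e^{−k₂t}),
P_S0 = 1 − P_S2 − P_S1 (conservation exact by construction), with the
degenerate limit k·t·e^{−kt} taken when |k₁−k₂|/k₁ < 10⁻⁹. The prompt
channel detects a₂P_S2 + a₁P_S1 plus a constant baseline; the delayed
channel detects a₀P_S0 (ground-state recovery).

Convolution with a Gaussian instrument response of width σ (default
80 fs — the scale of a fs pump–probe cross-correlation) is closed-form
per exponential component (exponentially modified Gaussian). The EMG is
evaluated through erfcx with a switch to the asymptotic branch at
z < −20 so late delays of fast components cannot overflow. The convolved
P_S0 uses the convolved unit step minus the convolved excited-state
terms.

Fitting is weighted least squares (Levenberg–Marquardt via lmfit):

- lifetimes are optimized as log₁₀ τ (positivity by construction);
- t₀ and σ_IRF are optimized in picosecond units so the optimizer's
  finite-difference steps are sensibly scaled;
- τ_fast, τ_slow, t₀ and σ_IRF are shared between the prompt and delayed
  channels; amplitudes and baselines are per-channel;
- after convergence the labels are canonically ordered τ_fast ≤ τ_slow
  (detection weights swap along), removing label-switching from swapped
  initial guesses;
- non-convergence and degenerate (constant) data return flagged results,
  never silent numbers; 1σ uncertainties come from the covariance at the
  optimum, back-transformed from log space.

On sparse delay grids the IRF width is weakly constrained, so recovery
studies hold it fixed at the generation value via the `fixed` parameter
set.

## Power-law analysis

The photon order n is the slope of log(yield) on log(pulse energy) —
exact on noiseless data for any n, robust at few points. With per-point
uncertainties the regression is weighted by the propagated log-domain
errors. Non-positive yields carry no log information and are dropped with
a logged count; fewer than three usable points is an error. Classification
accepts the nearest integer m ∈ {1, 2} when |n − m| ≤ max(2σₙ, 0.15); the
0.15 floor keeps sparse series with optimistically small formal errors
from over-claiming. Normalization divides by Pⁿ and is the exact inverse
of re-multiplication.

## 2D spectrum simulator

Each open channel adds a Gaussian ridge in eKE at its energetically
determined centre; the low-eKE channel adds exp(−eKE/decay); the
resonance channel widens the direct ridge (in quadrature) inside its
photon-energy window. Ridge width (default 0.15 eV) stands in for the
unmodelled instrument resolution and Franck–Condon envelopes. The output
is normalized to unit maximum (absolute counts are instrument-dependent);
per-channel contribution masks are kept so pixels can be attributed to
their generating process. Peak positions in 1D cuts use three-point
parabolic interpolation; exact ties resolve to the lower-eKE maximum.

## Synthetic data

Generators are pure functions of (parameters, seed) using
`numpy.random.default_rng`. Defaults encode the study conditions: the
reference kinetics (τ_fast 100 fs, τ_slow 94 ps, IRF σ 80 fs), 5%
multiplicative lognormal noise on transients (the visual scatter scale of
ion-yield data), a 60-point delay grid from −0.5 to 400 ps (linear through
the IRF region, then geometric — a pure geometric grid cannot contain
negative delays), and 78 vibrational modes uniform on 50–3500 cm⁻¹. The
transition-state variant removes the lowest mode and perturbs the rest by
a seeded ±10%.

What the generators do *not* emulate: correlated drifts, storage-ring
revolution structure, laser spectral profiles, detector saturation, and
real (non-uniformly-distributed, partly degenerate) vibrational spectra.
Passing recovery tests therefore demonstrates the correctness and
statistical calibration of the estimators under the stated noise model,
not their robustness to systematics absent from that model.

## Problem sizes

The test suite and the acceptance script use 100 fit replicates for the
recovery study, 50 random systems (≤ 12 modes, ≤ 10⁴ cm⁻¹) for the
counting-oracle equivalence, three 78-mode seeds for the lifetime-regime
check, and 140×250-pixel spectra for the classifier study — sizes at
which every quantity is statistically stable while the whole suite runs
in well under a minute.

## Known limitations

- Harmonic, rotation-free state counts; no master-equation collisional
  relaxation; no competition with vibrational autodetachment.
- The lifetime pipeline reuses one frequency set for S₀ and S₁ unless the
  caller supplies separate sets.
- The D₁ probe channel and photoelectron angular distributions are out of
  scope; the excited-neutral channel is modelled only through VDE(D₁ₙ).
- The delayed channel is fit as pure ground-state recovery, without
  separating thermionic emission from statistical fragmentation.
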