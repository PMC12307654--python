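# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `condensage`.

## Probe-trajectory models

All trajectory simulation is two-dimensional with uniform sampling. Defaults
mirror a spinning-disk acquisition of 100 nm-radius beads: dt = 0.02 s
(50 frames/s), 200 frames, pixel size 0.1 µm, T = 298.15 K.

* **Newtonian** (`D`, µm²/s): i.i.d. Gaussian increments with per-axis
  variance 2·D·dt; 2D MSD = 4Dτ.
* **Subdiffusive** (`alpha_true` ∈ (0, 1], `K` µm²/s^α): fractional Brownian
  motion per axis with Hurst index H = α/2, sampled *exactly* by Cholesky
  factorization of the stationary fractional-Gaussian-noise covariance
  γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})·dt^{2H}. fBm is the minimal
  stationary-increment Gaussian process with MSD = 4K·τ^α; no claim is made
  that a condensate's microstructure is literally fBm. Superdiffusion
  (α > 1) is rejected.
* **Jeffreys** (`D_free`, `plateau`, `tau_relax`): free diffusion plus a
  stationary Ornstein–Uhlenbeck confinement (per-axis variance plateau/4,
  exact exponential update), giving
  MSD = 4·D_free·τ + plateau·(1 − e^{−τ/τ_relax}). Within an experimental
  lag window that starts after τ_relax, this produces a caged-then-flowing
  MSD and exactly one G′/G″ crossover — the Maxwell-fluid phenotype.
  Probing much shorter lags would reveal the solvent-dominated (viscous)
  short-time branch; the demo parameters keep τ_relax below the first lag
  deliberately.

Localization noise is additive Gaussian on positions (sd per axis and
frame), the standard tracking-error model; it inflates the MSD by the
constant 4σ². Randomness is a single root seed feeding named PCG64 child
streams (`numpy.random.SeedSequence` spawn keys), so outputs are
reproducible bit-for-bit and stages do not perturb each other.

## MSD and diffusive exponent

`compute_msd` averages over *all* overlapping pairs within each track (time
average), then across tracks weighted by pair counts (ensemble average);
it equals the O(N²) brute-force estimator exactly and tolerates frame gaps
left by linking. Lags are kept up to `max_lag_fraction` (default 0.25) of
the longest track — beyond that the time average rests on too few pairs.

`fit_powerlaw` estimates the local exponent α(τ) by a quadratic fit in
log–log coordinates over a 7-point sliding window (Mason-style smoothing of
the derivative in the definition α = d ln MSD / d ln τ), and the long-time
exponent by a straight-line fit over a stated window (the analysis default
is the first decade of lags, where pair counts are highest);
D_app = e^{intercept}/4.

## GSER moduli and material state

The local-power-law GSER evaluates, at ω = 1/τ,
|G*| = 2k_BT / (C·a·MSD(τ)·Γ[1+α(τ)]) with phase πα/2. Two prefactor modes
exist because the bare 2k_BT/(a·MSD·Γ) form, applied to a 2D MSD, yields
G″ = 3πη·ω on a Newtonian fluid rather than η·ω. The default mode
(`stokes_einstein_consistent`, C = 3π) recovers Stokes–Einstein exactly and
is what every quantitative result uses; `literal` mode (C = 1) is retained
for side-by-side comparison with the bare form. α is clamped to [0, 1]
before the phase factor — the probe regime of interest is sub- to
normal-diffusive, and α > 1 would produce negative G′. Units: k_BT in J,
bead radius and MSD converted to m/m², moduli in Pa.

`find_crossover` median-smooths log G′ − log G″ (3 points) and reads the
sign pattern: all negative → viscous, all positive → elastic, one change
with G″ dominant at low ω → Maxwell, with ω_c interpolated linearly in
log–log and τ_c = 1/ω_c. Multiple crossings fall back to the
lowest-frequency one with a warning; a crossing with G′ dominant at low
frequency is reported elastic (it is not the aging signature).
`classify_timecourse` flags whether an age-ordered state sequence is
monotone along viscous → maxwell → elastic.

## Tracking

Detection: difference of Gaussians at σ and 3σ, local maxima above the
band-passed frame's mean + `threshold_sd`·sd, sub-pixel refinement by
intensity-weighted centroid in a (2⌈3σ⌉+1)² window with background-clipped
weights. Spots whose window exits the frame are discarded (edge bias).
Linking: per frame pair, Hungarian assignment on squared displacements gated
at `max_displacement` (infeasible pairs get a sentinel cost), deterministic
tie-breaking; tracks dark for ≤ `memory` frames re-link at their last
position; tracks shorter than `min_track_length` are dropped. Centroid
errors are slightly correlated between adjacent frames (pixel-locking), so
the 4σ² MSD offset saturates over the first couple of lags; tests estimate
it as the median excess over ground truth.

## FRAP

The chain implements C_f(t) = R_i/R(t), I_cor = C_f·I,
I_n = (I_cor − I_min)/(I_i − I_min), F_im = (I_i − I_∞)/(I_i − I_min),
F_m = 1 − F_im (exact identity), the single-exponential fit
I_n(t) = F_m(1 − e^{−ln2·t/τ½}) with analytic initial guesses and bounds
F_m ∈ [0, 1.2], and D_app = 0.22 r²/τ½. Choices the equations leave open:
I_i is the mean of *all* pre-bleach corrected frames; I_min is the first
post-bleach frame; fits are unweighted with time re-zeroed at the bleach
frame; I_∞ defaults to the fitted asymptote (robust to end-of-trace noise)
with a `last`-frame option; I_∞ may exceed I_i by 2% (noise headroom) before
being clipped with a warning. A flat trace yields F_m = 0 with τ½ flagged
unidentifiable. The generator applies a single-exponential acquisition
bleach to ROI and reference alike — the one model for which reference-based
correction is exact, which is what makes the correction stage provable.
Note that D_app from this formula is tied to the *bleach-spot* radius; with
r = 1 µm and τ½ = 0.5 s it gives 0.44 µm²/s, so absolute D_app values from
differently calibrated spot radii are not comparable.

## Kinetics

Concentration = (A − blank)/slope with negatives floored at 0 (warned).
Initial rates are OLS slopes over the early window — default the first 20%
of points, minimum 3; the generator produces strictly linear early-time
traces (substrate depletion is not modelled), so recovery tests may use the
full trace. Michaelis–Menten and logistic fits are unweighted
Levenberg–Marquardt with analytic guesses (Vmax = max v, K_M = S at
half-max; logistic k from 4·max-slope/amplitude) and positivity bounds;
both are exact on noiseless model data. A fitted K_M more than 100× outside
the sampled substrate range is flagged unidentifiable. Relative rates are
plain ratios against the control (1 = parity), reciprocal by construction.

## Imaging

Segmentation thresholds the scaffold channel (Otsu default — invariant to
global intensity scaling), labels 8-connected components, and removes
components under `min_area_px` (default 9 px, to suppress shot noise). A
contrast guard rejects the mask when foreground exceeds background by less
than 4 background-sd — Otsu otherwise bisects pure noise on condensate-free
fields. The enrichment index pools all condensate pixels against background
pixels outside a 2 px dilated halo (edge-blur exclusion); a per-condensate
averaging mode is available behind a flag since the field convention is
ambiguous. Line profiles sample bilinearly, average over the profile width,
min–max normalize each channel, and report the Pearson correlation; a
constant channel degenerates to a zero profile with a flag.

## Pipeline and problem sizes

`run_pipeline` validates a strict (unknown-key-rejecting) pydantic config,
runs generate/ingest → microrheology ∥ FRAP ∥ kinetics ∥ imaging per age
point, writes every intermediate CSV/JSON artifact, and stamps each report
row with the SHA-256 hash of the configuration and the seed. Re-running
against an unchanged configuration returns the stored report (whole-run
granularity) unless forced. The demo time course uses 300 tracks × 200
frames per age point and parameterizes the three ages as a viscous liquid
(α ≈ 0.8), a Maxwell fluid (τ_c ≈ 0.1 s) and an elastic solid (α ≈ 0.02),
with FRAP immobile fractions 28.8/50.8/97.4% and reaction rates
18.7/13.2/2.13 µM/min against their controls. Test ensembles range from
500 tracks (exponent recovery) to 10⁴ (distributional checks); these sizes
put sampling error comfortably inside the stated tolerances while keeping
the suite fast.

## What the synthetic data does and does not show

The generators reproduce the *statistical structure* the estimators assume:
Gaussian processes with the stated MSDs, exponential photobleaching shared
by ROI and reference, strictly linear early-time progress curves, flat-top
condensates with exact interior/exterior ratios, Poisson-background video
with Gaussian PSFs. Passing tests therefore demonstrate estimator
correctness and pipeline integrity — not robustness to real-microscopy
pathologies such as drift, uneven illumination, camera-specific noise
(EMCCD gain), reaction–diffusion FRAP geometry, substrate depletion, or
out-of-focus light. Known limitations by design: no 3D trajectories, no
two-point microrheology, no frequency extrapolation beyond the reciprocal
lag window, no two-component FRAP fits, no machine-learned segmentation.
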