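# Methods

This note documents the models, numerical choices and conventions behind
`cftrpot`, what the synthetic-data generators do and do not emulate, and
the package's known limitations.

## Gating schemes and their assumptions

The four schemes in `cftrpot.schemes` describe reversible channel
potentiation by a lipophilic drug applied to the cytosolic face of an
excised inside-out patch. Shared assumptions:

- The bath (cytosolic) drug concentration `V_c(t)` is piecewise constant
  (perfusion switching is treated as instantaneous) and is never present on
  the pipette (extracellular) side; the pipette volume is effectively
  infinite, so drug leaving the outer membrane surface is lost.
- Drug partitioning is first order: entry flux `k_in·V_c` into the
  membrane, exit `k_out` from each leaflet (hence the factor 2 in the
  single-compartment schemes, which lump both leaflets), symmetric
  inter-leaflet flip-flop `k_flip` in the two-compartment schemes.
- Binding sites are independent and identical (`2·k_on'`/`k_off`
  statistical factors for the two-site schemes), and only the fully
  liganded channel gates at the potentiated open probability. Channel
  gating itself is assumed fast relative to drug movement, so the current
  tracks state occupancies instantaneously.
- Fully liganded channel concentration is represented implicitly as
  `C_t − Σ(explicit channel states)`; channel mass conservation is
  therefore exact by construction, and the integrator additionally asserts
  non-negativity of all components.

The pre-drug initial condition is: drug compartments empty, the entire
channel pool unliganded. This makes the normalized current start exactly
at 1, consistent with normalizing experimental traces to their pre-drug
steady level. (Starting the channel pool anywhere else would contradict
that normalization.) Washout segments inherit the final state of the
preceding segment.

## Integration

The ODEs are integrated with Heun's predictor-corrector (the common
reading of "modified Euler"), a fixed-step second-order method; step
halving on the reference trace changes samples by < 1e-4 relative at the
default step (asserted by a step-refinement test). The user step (default 10 ms; the ensemble fitter uses 50 ms) is
capped at `0.1 / max(2·k_out, k_off, 2·k_flip, k_on'·V̂_m, 2·k_on'·C_t)`,
where `V̂_m` is the steady-state membrane concentration at the protocol's
highest concentration — i.e. a tenth of the fastest effective first-order
time constant, keeping the explicit scheme well inside its stability
region while a 20-minute protocol stays around 2·10⁴ steps. Within each
protocol segment the step is rounded down so segment boundaries fall
exactly on the grid. Per-scheme scalar-unrolled inner loops are the hot
path of the ensemble fit; a test asserts they reproduce the generic
`rhs`-based Heun step to round-off.

## Channel-site concentration conventions

`C_t = N/(N_A·V)` with the membrane volume `V = 1e-16 L` for the
single-compartment schemes and the outer-leaflet volume `5e-17 L` for the
two-compartment schemes; `N` is estimated from the pre-drug mean current
assuming a basal open probability of 0.16. Both volumes are overridable.
Refits with 5-fold different volumes leave `po_ratio` essentially
unchanged and shift `k_off` by only a few percent, with `k_on'`
absorbing the rescaling — note that at strongly reduced volumes the
channel sites become a non-negligible sink for the membrane drug pool at
subnanomolar bath concentrations, which is a real (small) model effect,
not a fitting artifact.

## Ensemble fitting

Plain (unweighted) least squares over all samples of all traces, each
trace's protocol integrated on the configured step and interpolated onto
its time grid. Free parameters: `k_out`, `k_on'`, `k_off`, `po_ratio`
(plus `k_flip` for two-compartment schemes); `k_in` is reconstructed as
`k_out · D` at every evaluation, with `D = 62580` the octanol/water
distribution coefficient at pH 7.1 (the printed constant is kept rather
than the ratio of rounded solubilities, 3.9e-3/6.2e-8 ≈ 62900, which
differs by rounding).

Rates are optimized as logarithms (positivity without penalties; they span
five decades) and the open-probability ratio as `log(po_ratio − 1)`. The
minimizer is Nelder-Mead with an explicit initial simplex of fixed spread
0.25 in log space — the conventional value-proportional simplex collapses
when a log coordinate sits near zero — and is restarted from the incumbent
best point with a fresh simplex until the SSE stops improving (at most
five runs within the evaluation budget, default 5000). Restarts matter:
with five free parameters a single simplex run reproducibly stalls short
of the optimum. Convergence tolerances: `xatol` 1e-6 on log parameters,
`fatol` equal to the configured SSE tolerance (default 1e-8). Default
initial guesses when none are supplied: `k_out = 0.1 s⁻¹`,
`k_on' = 10³ M⁻¹s⁻¹`, `k_off = 0.01 s⁻¹`, `po_ratio` = plateau of the
highest-concentration trace, `k_flip = k_out`.

## Empirical relaxation analysis

- `tau_on_star`: plateau = mean of the final 10% of the segment (required
  to be stable within 2%); `τ_on* = T_1/2/ln 2` with the half-crossing
  found by linear interpolation. Exact for a pure exponential.
- Three-step activation chain S1→S2→S3→S4: occupancy of S4 is the
  hypoexponential CDF evaluated in closed form, with dedicated branches
  when rates coincide within 1e-6 relative (the generic partial-fraction
  form cancels catastrophically there). The basal level of S1-S3 is fixed
  at the normalized pre-drug current (1); the terminal fold-stimulation
  may be fixed or free.
- Deactivation: single exponential with free offset (the level the current
  relaxes back to). Washout fits give τ_off ≈ 1.4 min for the reference
  parameter set. The concentration-independence of the deactivation rate
  is a statement about the binding-limited phase: immediately after a
  saturating exposure the decay is transiently slowed by rebinding while
  the free membrane pool (time constant `1/(2·k_out)` ≈ 8 s) empties, so
  the independence property is evaluated from `5/(2·k_out)` after removal,
  where washout rates after 0.01x and 1x exposures agree within a percent
  and equal `2·k_off` (two bound drug molecules, either may leave first).

## Single-channel analysis

Idealization assigns each sample the number of half-amplitude thresholds
`(k−½)·i_unitary` exceeded, run-length encodes, and merges runs shorter
than the 6-ms dead time into the preceding event (a short leading run goes
into the following one). Baseline is assumed drift-free at level 0.

The C-O-B dwell-time likelihood (single-channel records only) treats open
dwells as exponential with rate `r_OC + r_OB` and shut dwells as a
two-exponential mixture (flicker component `r_BO`, interburst `r_CO`),
all left-truncated at the dead time, with a first-order missed-event
correction: sub-dead-time sojourns are folded into effective apparent exit
rates on both sides (a missed flicker extends the apparent open period; a
missed brief opening extends the apparent shut period). This is a
deliberate simplification of exact missed-event likelihoods; on simulated
records with realistic rates it recovers all four rates within ~10%
(bias ~5%), sufficient for the factor-level comparisons it supports.
Optimization reuses the simplex in log-rate space with moment-based
starting values. Burst metrics: `τ_b = (1/r_OC)(1 + r_OB/r_BO)`,
`τ_ib = 1/r_CO`; the stationary open probability uses the detailed-balance
closed form of the linear three-state chain.

## Solubility and thermodynamics

Calibration is ordinary least squares with a free intercept (blank-
corrected spectra can retain small offsets). Extraction arithmetic is
exact inversion of the calibration and concentration factor. The gas
constant is taken as 8.31 J mol⁻¹K⁻¹ (two decimals) so the derived
quantities round to the conventional printed precision: with solubilities
62 nM at 298 K and 138 nM at 310 K, ΔH°_sol = +51.2 kJ/mol,
ΔG°_sol(298 K) = +41.1 kJ/mol (1 M standard state), TΔS° = +10.1 kJ/mol.
The two-point van't Hoff estimate assumes a temperature-independent ΔH
over the 12 K interval.

## Synthetic data

Generators are deterministic functions of (parameters, seed), and their
noiseless outputs are exact fixed points of the corresponding analysis
stage. Macroscopic noise is additive stationary Gaussian — real recordings
have open-channel (state-dependent) noise, but the downstream fits are
plain least squares, so stationary noise exercises the same estimator
paths; recovered parameters on real data would carry somewhat different
error bars. Single-channel records are continuous-time Markov simulations
of independent channels, sampled and summed; dose-response replicates use
multiplicative Gaussian noise of fixed CV. Passing tests therefore
demonstrate correctness of the estimators under the models' own
assumptions, not robustness to baseline drift, rundown, or filtering
artifacts of real recordings.

## Problem sizes used in tests and the acceptance script

The parameter-recovery experiment integrates 10-min-on/10-min-off
protocols at 0.62 and 62 nM on a 50-ms step sampled every 2 s (~1200
observations; the fit takes ~300-900 objective evaluations). Generic
recovery and model-comparison tests use a milder parameter set (5-min
segments, 0.1-s step) chosen so the stiffest pseudo-first-order rate stays
near 0.6 s⁻¹ and a fit completes in seconds. Single-channel rate recovery
uses 3000-s records (~27k events); stochastic checks use fixed seeds.

## Known limitations

- No stochastic channel-number fluctuations in the macroscopic model, no
  lateral diffusion, no extracellular drug application.
- The C-O-B likelihood's missed-event treatment is first order; exact
  corrections would remove the remaining ~5% bias. Multi-channel records
  get open-probability and stability analysis only.
- No confidence intervals on fitted parameters (point estimates only);
  uncertainty across patches is expected to be summarized as mean ± SEM by
  the user.
- Supersaturation and intra-membrane precipitation are outside the model:
  all concentrations are assumed at or below saturation.
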