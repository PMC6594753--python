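# cftrpot

Quantitative analysis of CFTR-potentiator action in cell-free membrane
patches: how a highly lipophilic drug (ivacaftor-class potentiators)
partitions into the membrane, binds the channel, and reversibly raises its
open probability — and why its apparent aqueous potency is subnanomolar
even though its intramembrane affinity is micromolar.

The package is written for ion-channel biophysicists and pharmacologists
who need to (i) fit mechanistic partition/binding models to macroscopic
current relaxations, (ii) analyze dose-response curves and single-channel
gating records, and (iii) handle the solubility and partition
thermodynamics of drugs whose aqueous solubility is in the nanomolar range.

## The models

**Gating schemes.** Four compartmental kinetic schemes describe the drug's
path from the cytosolic bath to the channel: one or two drug binding sites,
crossed with one or two membrane compartments (leaflets). The drug enters
the membrane at rate `k_in·V_c` (V_c the cytosolic concentration), leaves
each leaflet at `k_out`, optionally flips between leaflets at `k_flip`, and
binds each channel site with second-order rate `k_on'` and leaves it at
`k_off`. Only fully liganded channels gate at the potentiated open
probability, `po_ratio = P_o;max/P_o;bas`-fold above basal. The state
vector of compartment concentrations **x**(t) follows mass-action ODEs
integrated with a fixed-step Heun ("modified Euler") method, and the
normalized current is `1 + (po_ratio − 1)·(potentiated fraction)`.

**Steady-state theory.** For the single-compartment schemes the membrane
drug accumulates to `V_m;∞ = V_c·k_in/(2·k_out)`; the channel pool then
equilibrates with occupancy `Y1 = V/(K_d;mem + V)` (one site) or
`Y2 = Y1²` (two sites), `K_d;mem = k_off/k_on'`. Two-site activation has
midpoint `K_0.5;mem = (1+√2)·K_d;mem` and an apparent Hill slope of
`2·(2−√2) ≈ 1.17` — a testable signature of two independent sites. The
aqueous midpoint is `K_0.5;aq = K_0.5;mem/(k_in/(2·k_out))`.

**Ensemble fitting.** A single parameter set is fitted simultaneously to a
set of normalized on/off current time courses by (restarted) downhill
simplex least squares in log-parameter space, with `k_in/k_out` pinned to
the measured octanol/water distribution coefficient (D = 62580 at pH 7.1),
which removes the partition-step degeneracy.

**Other components.** Modified-Hill dose-response fitting
(`I/I_ctrl = (K^n + R·c^n)/(K^n + c^n)`); single-exponential deactivation
and an empirical three-step activation chain with `τ_on* = T_1/2/ln 2`;
half-amplitude idealization of single-channel records and dwell-time
maximum likelihood for the closed-open-blocked (C-O-B) gating scheme with a
6-ms dead time; spectrophotometric calibration/extraction arithmetic and
two-point van't Hoff solution thermodynamics. Seeded generators in
`cftrpot.synth` emulate every input, so the whole pipeline is testable
without laboratory data.

## Worked example

Steady-state theory with the reference wild-type parameter set
(`python examples/steady_state_theory.py`):

```
membrane drug at 1x saturation: 1.94 mM (31291-fold accumulation)
steady-state stimulation at 1x: 3.91-fold
K_d;mem   = 8.56 uM   (intramembrane dissociation)
K_0.5;mem = 20.67 uM  (= (1+sqrt(2)) K_d;mem)
K_0.5;aq  = 0.66 nM   (apparent aqueous affinity)
midpoint Hill slope (closed form): 1.1716
Hill fit to the theory curve: K_0.5 = 0.67 nM, n_H = 1.24, max 3.89-fold
```

A 62 nM (saturated) bath concentration accumulates ~31000-fold in the
membrane to ~2 mM, saturating both micromolar-affinity intramembrane sites:
the apparent aqueous potency is therefore subnanomolar (0.66 nM), and the
predicted steady stimulation at saturation is ~4-fold. The Hill slope of
the two-site activation curve is ~1.17, not 2.

The other scripts in `examples/` demonstrate one capability each: ensemble
fitting (`simulate_and_fit_ensemble.py`), activation/deactivation kinetics
(`activation_deactivation.py`), single-channel analysis
(`single_channel_gating.py`), extraction-based solubility determination
(`solubility_extraction.py`) and solution thermodynamics
(`solution_thermodynamics.py`). A thin `cftrpot` command-line interface
wraps the same functions for shell use (`cftrpot --help`).

## Layout

```
src/cftrpot/
  schemes.py    # gating schemes: ODEs, integrator, steady-state theory
  ensemble.py   # trace normalization, global simplex ensemble fitting
  response.py   # Hill, exponential decay, three-step chain, tau_on*
  gating.py     # idealization, P_o, stability windows, C-O-B likelihood
  thermo.py     # calibration, extraction, partition, van't Hoff
  synth.py      # seeded generators for every input type
  io.py         # plain-text trace/event/table formats
  cli.py        # thin click CLI
```

Methodological details, parameter conventions and known limitations are
documented in `docs/methods.md`.
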