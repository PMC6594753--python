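"""Empirical kinetics of drug application and washout.

Simulates the macroscopic response of the two-site scheme to a low-
concentration application, then characterizes it model-free: the apparent
activation time constant tau_on* (half-rise time over ln 2), an empirical
irreversible three-step chain for the sigmoidal onset, and a single
exponential for the washout decay.
"""

import numpy as np

from cftrpot import (
    DrugProtocol,
    GatingParams,
    Scheme,
    channel_site_concentration,
    fit_exponential_decay,
    fit_three_step_activation,
    integrate_protocol,
    tau_on_star,
)

params = GatingParams(k_in=4034.0, k_out=0.06446, k_on=870.3, k_off=0.007451,
                      po_ratio=3.935,
                      c_t=channel_site_concentration(100, 1e-16))

t_on, t_off = 900.0, 900.0
for conc, label in ((0.62e-9, "0.01x"), (62e-9, "1x")):
    protocol = DrugProtocol.on_off(conc, t_on, t_off)
    sim = integrate_protocol(Scheme.TWO_SITE, params, protocol, dt=0.05,
                             record_every=40)
    on = sim.t <= t_on
    off = sim.t >= t_on

    tstar = tau_on_star(sim.t[on], sim.i_norm[on])
    chain = fit_three_step_activation(sim.t[on], sim.i_norm[on])
    decay = fit_exponential_decay(sim.t[off], sim.i_norm[off])

    print(f"{label:5s} saturated ({conc * 1e9:.2f} nM):")
    print(f"  tau_on* = {tstar:7.1f} s   (activation rate "
          f"{1 / tstar:.4f} s^-1)")
    print(f"  three-step chain rates: {chain.k12:.3g}, {chain.k23:.3g}, "
          f"{chain.k34:.3g} s^-1 (plateau {chain.po_s4_ratio:.2f}-fold)")
    print(f"  washout: tau_off = {decay.tau:5.1f} s   (rate "
          f"{decay.rate:.4f} s^-1)")

print()
print("Activation is strongly concentration dependent (slower at 0.01x,")
print("with a sigmoidal delay needing three sequential steps), while the")
print("washout time constant (~1.5 min) barely changes: deactivation is")
print("rate-limited by drug unbinding, not by washout of the membrane pool.")
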