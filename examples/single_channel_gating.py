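"""Single-channel gating analysis with the closed-open-blocked scheme.

Simulates a single channel gating by the C-O-B scheme (long interburst
closures to C, brief flickery closures to B), idealizes a noisy sampled
record by half-amplitude threshold crossing, and recovers open probability,
stability windows, the microscopic rates by dwell-time maximum likelihood,
and the burst metrics.
"""

from cftrpot import (
    COBRates,
    burst_summary,
    cob_stationary_po,
    fit_cob,
    gaussian_filter,
    idealize,
    open_probability,
    stability_windows,
)
from cftrpot.synth import gen_cob_events, gen_single_channel

rates = COBRates(r_co=0.84, r_oc=0.82, r_ob=18.0, r_bo=110.0)
print(f"generating rates: r_CO={rates.r_co}, r_OC={rates.r_oc}, "
      f"r_OB={rates.r_ob}, r_BO={rates.r_bo} s^-1")
print(f"stationary P_o = {cob_stationary_po(rates):.3f}")

# a short noisy sampled record, filtered and idealized
trace = gen_single_channel(rates, duration=120.0, sampling_rate=1000.0,
                           unitary_current=1.0, sd=0.15, seed=42)
filtered = gaussian_filter(trace, 50.0)
events = idealize(filtered, unitary_current=1.0, dead_time=6e-3)
print(f"\nidealized {trace.duration:.0f} s record: {events.levels.size} "
      f"events, P_o = {open_probability(events):.3f}")
print("P_o per 46-s window:",
      [f"{po:.2f}" for po in stability_windows(events, 46.0)])

# rate estimation needs a longer event record
long_events = gen_cob_events(rates, duration=3000.0, seed=7)
fit = fit_cob(long_events)
print(f"\nML rates from a 3000-s record ({long_events.levels.size} events):")
for name in ("r_co", "r_oc", "r_ob", "r_bo"):
    got, want = getattr(fit, name), getattr(rates, name)
    print(f"  {name}: {got:8.3g}  (true {want}, {(got / want - 1) * 100:+.1f}%)")

summary = burst_summary(fit)
print(f"\nburst metrics: tau_b = {summary.tau_b:.2f} s, "
      f"tau_ib = {summary.tau_ib:.2f} s")
print(f"opening rate = {summary.opening_rate:.2f} s^-1, "
      f"closing rate = {summary.closing_rate:.2f} s^-1")
print()
print("Flickery closures shorter than the 6-ms dead time are merged during")
print("idealization; the dwell-time likelihood corrects for them to first")
print("order, recovering all four microscopic rates within ~10%.")
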