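"""Seeded generators emulating every input the analysis pipeline consumes.

Each generator is a deterministic function of its parameters and a seed, and
its noiseless output is an exact fixed point of the corresponding analysis
stage: a noiseless macroscopic trace normalizes back to the model
prediction, noiseless dose-response points lie exactly on the Hill curve,
and a noiseless extraction round-trips the true solubility.

Macroscopic noise is additive, stationary Gaussian.  Real recordings have
state-dependent (open-channel) noise, but the downstream fits are plain
least squares, for which stationary noise exercises the same code paths.
"""

from __future__ import annotations

import numpy as np

from .gating import COBRates, CurrentTrace, EventList, _merge_short_dwells
from .response import DoseResponsePoint, hill_curve
from .schemes import DrugProtocol, GatingParams, Scheme, integrate_protocol
from .thermo import CalibrationCurve
from . import constants

__all__ = [
    "gen_macroscopic",
    "gen_cob_dwells",
    "gen_cob_events",
    "gen_single_channel",
    "gen_dose_response",
    "gen_extraction_experiment",
]


def gen_macroscopic(
    scheme: Scheme,
    params: GatingParams,
    protocol: DrugProtocol,
    amplitude: float = 1.0,
    sd: float = 0.0,
    seed: int = 0,
    dt: float = 0.05,
    record_every: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw macroscopic current trace: amplitude * i_norm(t) + Gaussian noise.

    Returns ``(t, current)``.  With ``sd = 0`` and ``amplitude = 1`` the
    output equals the integrated normalized trace sample for sample.
    """
    sim = integrate_protocol(scheme, params, protocol, dt=dt,
                             record_every=record_every)
    current = amplitude * sim.i_norm
    if sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, sd, size=current.size)
    return sim.t, current


def gen_cob_dwells(
    rates: COBRates, duration: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-time Markov simulation of one C-O-B channel.

    Returns ``(states, dwells)`` with states coded 0 = C, 1 = O, 2 = B,
    starting in C, truncated exactly at ``duration``.
    """
    rng = np.random.default_rng(seed)
    states = []
    dwells = []
    state = 0
    t = 0.0
    while t < duration:
        if state == 0:
            rate, nxt = rates.r_co, 1
        elif state == 2:
            rate, nxt = rates.r_bo, 1
        else:
            rate = rates.r_oc + rates.r_ob
            nxt = 2 if rng.random() < rates.r_ob / rate else 0
        dwell = rng.exponential(1.0 / rate)
        dwell = min(dwell, duration - t)
        states.append(state)
        dwells.append(dwell)
        t += dwell
        state = nxt
    return np.array(states), np.array(dwells)


def gen_cob_events(
    rates: COBRates,
    duration: float,
    seed: int = 0,
    dead_time: float = constants.DEAD_TIME,
) -> EventList:
    """Idealization-equivalent event list from a simulated C-O-B channel.

    Conductance levels are 1 for O and 0 for both shut states; sub-dead-time
    dwells are merged into the preceding event, exactly as the half-amplitude
    idealizer would.
    """
    states, dwells = gen_cob_dwells(rates, duration, seed)
    levels = (states == 1).astype(int)
    # collapse C/B runs that map to the same conductance level
    lv: list[int] = []
    du: list[float] = []
    for l, d in zip(levels, dwells):
        if lv and l == lv[-1]:
            du[-1] += d
        else:
            lv.append(int(l))
            du.append(float(d))
    return _merge_short_dwells(lv, du, dead_time, n_channels=1)


def gen_single_channel(
    rates: COBRates,
    n_channels: int = 1,
    duration: float = 100.0,
    sampling_rate: float = 1000.0,
    unitary_current: float = 1.0,
    sd: float = 0.0,
    seed: int = 0,
) -> CurrentTrace:
    """Sampled current record of ``n_channels`` independent C-O-B channels.

    Each channel is simulated as a continuous-time Markov chain, its
    open/shut state sampled onto the uniform grid, the channels summed,
    scaled by the unitary current, and Gaussian noise added.
    """
    n_samples = int(round(duration * sampling_rate))
    t = np.arange(n_samples) / sampling_rate
    total = np.zeros(n_samples)
    for ch in range(n_channels):
        states, dwells = gen_cob_dwells(rates, duration, seed=seed * 1000 + ch)
        edges = np.concatenate(([0.0], np.cumsum(dwells)))
        idx = np.searchsorted(edges, t, side="right") - 1
        idx = np.clip(idx, 0, states.size - 1)
        total += (states[idx] == 1)
    current = unitary_current * total
    if sd > 0:
        rng = np.random.default_rng(seed + 777)
        current = current + rng.normal(0.0, sd, size=n_samples)
    return CurrentTrace(current, sampling_rate)


def gen_dose_response(
    k05: float,
    n_hill: float,
    imax_ratio: float,
    conc_grid: np.ndarray,
    replicates: int = 5,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> list[DoseResponsePoint]:
    """Dose-response points from the modified Hill curve with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv`` per replicate."""
    rng = np.random.default_rng(seed)
    points = []
    for c in np.asarray(conc_grid, dtype=float):
        true = float(hill_curve(c, k05, n_hill, imax_ratio))
        if noise_cv > 0:
            reps = true * (1.0 + rng.normal(0.0, noise_cv, size=replicates))
        else:
            reps = np.full(replicates, true)
        sem = float(reps.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else None
        points.append(
            DoseResponsePoint(conc=c, stimulation=float(reps.mean()),
                              sem=sem, n=replicates)
        )
    return points


def gen_extraction_experiment(
    s_true: float,
    concentration_factor: float,
    cal: CalibrationCurve,
    sd: float = 0.0,
    seed: int = 0,
) -> tuple[float, float]:
    """Optical densities of a first and second extract of a saturated stock.

    The first extract holds all the drug, concentrated by the volume ratio;
    the second extract is blank (a flat spectrum), confirming the first
    round extracted everything.
    """
    od1 = cal(s_true * concentration_factor)
    od2 = cal(0.0)
    if sd > 0:
        rng = np.random.default_rng(seed)
        od1 += rng.normal(0.0, sd)
        od2 += rng.normal(0.0, sd)
    return float(od1), float(od2)
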