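"""Single-channel record idealization and gating-kinetics analysis.

A patch current record containing one or a few channels is low-pass
filtered, idealized by half-amplitude threshold crossing into an event list
(conductance level, dwell duration), and summarized: open probability,
open-probability stability over consecutive windows, and -- for
single-channel records -- maximum-likelihood rates of a three-state
closed-open-blocked (C-O-B) scheme:

            r_CO          r_OB
        C <------> O <--------> B
            r_OC          r_BO

State B collects brief (~10 ms) "flickery" closures that interrupt open
bursts; state C the long (~1 s) interburst closures.  Mean burst and
interburst durations follow as ``tau_b = (1/r_OC)(1 + r_OB/r_BO)`` and
``tau_ib = 1/r_CO``, and channel opening/closing rates as their inverses.

Dwells shorter than the recording dead time are unresolvable; idealization
merges them into the preceding event, and the dwell-time likelihood uses
left-truncated exponential mixtures with a first-order missed-event
correction (sub-dead-time sojourns folded into an effective apparent
open-exit rate).  This is a deliberate simplification of exact
missed-event likelihoods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

from . import constants

__all__ = [
    "CurrentTrace",
    "EventList",
    "COBRates",
    "GatingSummary",
    "gaussian_filter",
    "idealize",
    "open_probability",
    "stability_windows",
    "fit_cob",
    "burst_summary",
    "cob_stationary_po",
]


@dataclass
class CurrentTrace:
    """Uniformly sampled current record."""

    current: np.ndarray
    sampling_rate: float
    filter_corner: float | None = None

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.filter_corner is not None and (
            self.sampling_rate < 2.0 * self.filter_corner
        ):
            raise ValueError("sampling_rate must be >= 2 * filter_corner")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.current.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.current.size / self.sampling_rate


@dataclass
class EventList:
    """Idealized record: ordered (conductance level, dwell duration) pairs.

    Levels count simultaneously open channels (0..n_channels); adjacent
    events always differ in level and every dwell is at least the dead time.
    """

    levels: np.ndarray
    durations: np.ndarray
    dead_time: float = constants.DEAD_TIME
    n_channels: int = 1

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.levels.shape != self.durations.shape:
            raise ValueError("levels and durations must have equal length")
        if self.levels.size == 0:
            raise ValueError("event list is empty")
        if np.any(self.durations < self.dead_time - 1e-12):
            raise ValueError("all dwells must be >= dead_time")
        if np.any(self.levels < 0) or np.any(self.levels > self.n_channels):
            raise ValueError("levels must lie in [0, n_channels]")
        if np.any(np.diff(self.levels) == 0):
            raise ValueError("adjacent events must differ in level")

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())


@dataclass(frozen=True)
class COBRates:
    """Microscopic transition rates (s^-1) of the C-O-B scheme."""

    r_co: float
    r_oc: float
    r_ob: float
    r_bo: float

    def __post_init__(self) -> None:
        for name in ("r_co", "r_oc", "r_ob", "r_bo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class GatingSummary:
    p_open: float
    tau_b: float
    tau_ib: float

    @property
    def opening_rate(self) -> float:
        return 1.0 / self.tau_ib

    @property
    def closing_rate(self) -> float:
        return 1.0 / self.tau_b


def gaussian_filter(trace: CurrentTrace, corner: float) -> CurrentTrace:
    """Zero-phase Gaussian low-pass filter with -3 dB point at ``corner`` Hz.

    The Gaussian kernel's transfer function is exp(-2 pi^2 sigma^2 f^2);
    setting it to 1/sqrt(2) at the corner gives
    sigma_t = sqrt(ln 2) / (2 pi f_c) ~ 0.1325 / f_c.  DC gain is 1.
    """
    if corner >= trace.sampling_rate / 2.0:
        raise ValueError("corner frequency must be below Nyquist")
    sigma_samples = math.sqrt(math.log(2.0)) / (2.0 * math.pi * corner) \
        * trace.sampling_rate
    filtered = gaussian_filter1d(trace.current, sigma_samples, mode="nearest")
    return CurrentTrace(filtered, trace.sampling_rate, filter_corner=corner)


def idealize(
    trace: CurrentTrace,
    unitary_current: float,
    n_channels: int = 1,
    dead_time: float = constants.DEAD_TIME,
) -> EventList:
    """Half-amplitude threshold idealization of a current record.

    Each sample is assigned the number of half-amplitude thresholds
    ``(k - 1/2) * unitary_current`` it exceeds; runs shorter than the dead
    time are merged into the preceding event (the leading run, if short,
    into the following one).
    """
    if unitary_current <= 0:
        raise ValueError("unitary_current must be positive")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    levels = np.clip(
        np.floor(trace.current / unitary_current + 0.5).astype(int),
        0,
        n_channels,
    )
    # run-length encode
    change = np.nonzero(np.diff(levels))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [levels.size]))
    run_levels = levels[starts].tolist()
    run_durs = ((ends - starts) / trace.sampling_rate).tolist()
    return _merge_short_dwells(run_levels, run_durs, dead_time, n_channels)


def _merge_short_dwells(
    levels: list[int], durations: list[float], dead_time: float, n_channels: int
) -> EventList:
    """Concatenation rule: absorb sub-dead-time runs into their predecessor."""
    out_lv: list[float] = []
    out_du: list[float] = []
    for lv, du in zip(levels, durations):
        if du < dead_time and out_lv:
            out_du[-1] += du
        elif out_lv and lv == out_lv[-1]:
            out_du[-1] += du
        else:
            out_lv.append(lv)
            out_du.append(du)
    # a short leading run that was kept only for lack of a predecessor
    while len(out_lv) > 1 and out_du[0] < dead_time:
        out_du[1] += out_du[0]
        del out_lv[0], out_du[0]
        if len(out_lv) > 1 and out_lv[0] == out_lv[1]:
            out_du[0] += out_du[1]
            del out_lv[1], out_du[1]
    # merging may have created equal neighbours; collapse them
    lv_arr: list[float] = []
    du_arr: list[float] = []
    for lv, du in zip(out_lv, out_du):
        if lv_arr and lv == lv_arr[-1]:
            du_arr[-1] += du
        else:
            lv_arr.append(lv)
            du_arr.append(du)
    return EventList(np.array(lv_arr), np.array(du_arr),
                     dead_time=dead_time, n_channels=n_channels)


def open_probability(events: EventList) -> float:
    """Time-averaged fraction of open channels."""
    total = events.total_duration
    if total <= 0:
        raise ValueError("event list has zero duration")
    weighted = float((events.levels * events.durations).sum())
    return weighted / (events.n_channels * total)


def stability_windows(
    events: EventList, window: float = constants.STABILITY_WINDOW
) -> np.ndarray:
    """Open probability over consecutive non-overlapping time windows.

    Events are split exactly at window boundaries; a partial final window is
    dropped.  Raises if the record is shorter than one window.
    """
    total = events.total_duration
    n_win = int(total // window)
    if n_win < 1:
        raise ValueError("record shorter than one stability window")
    open_time = np.zeros(n_win)
    t = 0.0
    for lv, du in zip(events.levels, events.durations):
        t_end = t + du
        w = int(t // window)
        while w < n_win and t < t_end:
            seg_end = min(t_end, (w + 1) * window)
            open_time[w] += lv * (seg_end - t)
            t = seg_end
            w += 1
        t = t_end
    return open_time / (events.n_channels * window)


def cob_stationary_po(rates: COBRates) -> float:
    """Stationary open probability of the C-O-B scheme.

    The linear chain satisfies detailed balance, so
    pi_C : pi_O : pi_B = r_OC/r_CO : 1 : r_OB/r_BO.
    """
    return 1.0 / (1.0 + rates.r_oc / rates.r_co + rates.r_ob / rates.r_bo)


def burst_summary(rates: COBRates) -> GatingSummary:
    """Burst metrics of a C-O-B parameterization.

    A burst is an open episode including its flickery closures; its mean
    duration is ``tau_b = (1/r_OC)(1 + r_OB/r_BO)``, and the mean interburst
    (long closed) duration is ``tau_ib = 1/r_CO``.
    """
    tau_b = (1.0 / rates.r_oc) * (1.0 + rates.r_ob / rates.r_bo)
    tau_ib = 1.0 / rates.r_co
    return GatingSummary(p_open=cob_stationary_po(rates), tau_b=tau_b,
                         tau_ib=tau_ib)


# ----------------------------------------------------------------------------
# Dwell-time maximum likelihood for the C-O-B scheme.

def _cob_neg_loglik(
    theta: np.ndarray,
    open_dwells: np.ndarray,
    shut_dwells: np.ndarray,
    dead_time: float,
) -> float:
    r_co, r_oc, r_ob, r_bo = np.exp(theta)
    td = dead_time
    lam_o = r_oc + r_ob
    b = r_ob / lam_o  # open exits into B rather than C
    # probabilities that the entered shut state outlasts the dead time
    p_b_seen = math.exp(-r_bo * td)
    p_c_seen = math.exp(-r_co * td)
    # fraction of open exits merged into the apparent open period
    merged = b * (1.0 - p_b_seen) + (1.0 - b) * (1.0 - p_c_seen)
    if merged >= 1.0 - 1e-12:
        return np.inf
    # first-order missed-event correction: merged sojourns extend the
    # apparent open period, so its exit rate is reduced accordingly
    lam_app = lam_o * (1.0 - merged)
    ll = open_dwells.size * math.log(lam_app) \
        - lam_app * float((open_dwells - td).sum())

    # symmetric correction on the shut side: an open sojourn shorter than
    # the dead time merges the flanking shut dwells, extending an apparent
    # B dwell when the chain re-enters B (probability b), and an apparent
    # C dwell when it re-enters C
    q_open = 1.0 - math.exp(-lam_o * td)
    r_bo_app = r_bo * (1.0 - q_open * b)
    r_co_app = r_co * (1.0 - q_open * (1.0 - b))
    w_b = b * p_b_seen
    w_c = (1.0 - b) * p_c_seen
    norm = w_b + w_c
    sd = shut_dwells - td
    dens = (w_b / norm) * r_bo_app * np.exp(-r_bo_app * sd) \
        + (w_c / norm) * r_co_app * np.exp(-r_co_app * sd)
    ll += float(np.log(np.maximum(dens, 1e-300)).sum())
    return -ll


def fit_cob(events: EventList) -> COBRates:
    """Maximum-likelihood C-O-B rates from a single-channel event list.

    Open dwells are exponential with rate ``r_OC + r_OB``; shut dwells are a
    two-component exponential mixture whose fast component (rate r_BO) holds
    the flickery closures and whose slow component (rate r_CO) the
    interburst closures.  All densities are left-truncated at the dead time
    and the apparent open-exit rate carries a first-order missed-event
    correction.  Rates are optimized with a downhill simplex in log space.
    """
    if events.n_channels != 1:
        raise ValueError("C-O-B rate fitting requires a single-channel record")
    if events.levels.size < 50:
        raise ValueError("need at least 50 events for a C-O-B fit")
    if events.levels.size < 200:
        warnings.warn("fewer than 200 events; C-O-B rates will be noisy",
                      stacklevel=2)
    open_dwells = events.durations[events.levels == 1]
    shut_dwells = events.durations[events.levels == 0]
    td = events.dead_time

    # moment-based starting point: split shut dwells into fast/slow classes
    split = max(5.0 * td, 1e-3)
    short = shut_dwells[shut_dwells < split]
    long = shut_dwells[shut_dwells >= split]
    r_bo0 = 1.0 / max(short.mean() - td, td / 2.0) if short.size else 10.0 / split
    r_co0 = 1.0 / max(long.mean() - td, split) if long.size else 0.1
    lam0 = 1.0 / max(open_dwells.mean() - td, td / 2.0)
    frac_b = short.size / max(shut_dwells.size, 1)
    frac_b = min(max(frac_b, 0.02), 0.98)
    theta0 = np.log([r_co0, lam0 * (1.0 - frac_b), lam0 * frac_b, r_bo0])

    res = minimize(
        _cob_neg_loglik,
        theta0,
        args=(open_dwells, shut_dwells, td),
        method="Nelder-Mead",
        options=dict(xatol=1e-8, fatol=1e-10, maxfev=5000),
    )
    if not res.success:
        warnings.warn("C-O-B likelihood maximization did not converge; "
                      "returning best point found", stacklevel=2)
    r_co, r_oc, r_ob, r_bo = np.exp(res.x)
    return COBRates(r_co=float(r_co), r_oc=float(r_oc), r_ob=float(r_ob),
                    r_bo=float(r_bo))
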