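"""Global ensemble fitting of gating schemes to on/off current time courses.

An experiment applies the drug to the cytosolic face of a patch at one or
more concentrations and records the macroscopic current relaxations during
application and washout.  After normalizing every trace to its pre-drug
steady level, a single parameter set of a chosen scheme is fitted
simultaneously to the whole ensemble by simplex least squares.

Identifiability of the membrane partition step is rescued by constraining
the entry/exit rate ratio to the drug's measured octanol/water distribution
coefficient: ``k_in = k_out * D`` throughout the fit.  Rate constants are
optimized in log space (positivity for free); the open-probability ratio is
optimized as ``log(po_ratio - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from . import constants
from .schemes import (
    DrugProtocol,
    GatingParams,
    Scheme,
    derived_affinities,
    integrate_protocol,
)

__all__ = [
    "ObservedTrace",
    "FitConfig",
    "FitResult",
    "normalize",
    "channel_site_concentration",
    "estimate_channel_count",
    "ensemble_objective",
    "fit_ensemble",
]


@dataclass
class ObservedTrace:
    """A normalized current time course with its drug protocol."""

    protocol: DrugProtocol
    t: np.ndarray
    i_norm: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i_norm = np.asarray(self.i_norm, dtype=float)
        if self.t.shape != self.i_norm.shape:
            raise ValueError("t and i_norm must have matching shapes")
        if self.t.size < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")


def normalize(
    t: np.ndarray,
    current: np.ndarray,
    pre_drug_window: tuple[float, float],
) -> np.ndarray:
    """Normalize a raw current trace to its pre-drug steady-state mean.

    ``pre_drug_window`` is a ``(t_start, t_stop)`` interval that must
    precede drug onset and contain at least one sample.
    """
    t = np.asarray(t, dtype=float)
    current = np.asarray(current, dtype=float)
    lo, hi = pre_drug_window
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError(f"pre-drug window [{lo}, {hi}] contains no samples")
    baseline = current[mask].mean()
    if baseline <= 0:
        raise ValueError("pre-drug mean must be positive for normalization")
    return current / baseline


def channel_site_concentration(n_channels: int, volume: float) -> float:
    """Channel-site concentration C_t = N / (N_A * volume), in M."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if volume <= 0:
        raise ValueError("volume must be positive")
    return n_channels / (constants.AVOGADRO * volume)


def estimate_channel_count(
    pre_drug_mean_current: float,
    unitary_current: float,
    po_bas: float = constants.PO_BASAL,
) -> int:
    """Channel count in a patch from its pre-drug mean current.

    Assumes every channel gates at the basal open probability, so
    ``N = I_mean / (i_unitary * P_o;bas)``, rounded, at least 1.
    """
    if pre_drug_mean_current <= 0 or unitary_current <= 0:
        raise ValueError("currents must be positive")
    if not (0 < po_bas <= 1):
        raise ValueError("po_bas must be in (0, 1]")
    return max(1, round(pre_drug_mean_current / (unitary_current * po_bas)))


@dataclass
class FitConfig:
    """Configuration of a global ensemble fit."""

    scheme: Scheme
    n_channels: int = 100
    d_ratio: float = constants.D_OCT_WAT
    compartment_volume: float | None = None  # default set per scheme
    initial_guess: dict[str, float] | None = None
    simplex_tolerance: float = 1e-8
    max_evaluations: int = 5000
    dt: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.scheme = Scheme(self.scheme)
        if self.d_ratio <= 0:
            raise ValueError("d_ratio must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.simplex_tolerance <= 0:
            raise ValueError("simplex_tolerance must be positive")
        if self.compartment_volume is None:
            self.compartment_volume = (
                constants.OUTER_LEAFLET_VOLUME
                if self.scheme.two_compartment
                else constants.MEMBRANE_VOLUME
            )

    @property
    def c_t(self) -> float:
        return channel_site_concentration(self.n_channels, self.compartment_volume)

    @property
    def free_names(self) -> tuple[str, ...]:
        base = ("k_out", "k_on", "k_off", "po_ratio")
        return base + ("k_flip",) if self.scheme.two_compartment else base


@dataclass
class FitResult:
    params: GatingParams
    sse: float
    derived: tuple[float, float, float]  # (K_d;mem, K_0.5;mem, K_0.5;aq)
    converged: bool
    n_evaluations: int
    scheme: Scheme
    config: FitConfig = field(repr=False)

    def to_json_obj(self) -> dict:
        kd, k05m, k05aq = self.derived
        return {
            "scheme": int(self.scheme),
            "params": {
                "k_in_per_s": self.params.k_in,
                "k_out_per_s": self.params.k_out,
                "k_on_per_M_s": self.params.k_on,
                "k_off_per_s": self.params.k_off,
                "k_flip_per_s": self.params.k_flip,
                "po_ratio": self.params.po_ratio,
                "c_t_M": self.params.c_t,
            },
            "derived": {"Kd_mem_M": kd, "K05_mem_M": k05m, "K05_aq_M": k05aq},
            "sse": self.sse,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "constants": {
                "d_ratio": self.config.d_ratio,
                "n_channels": self.config.n_channels,
                "compartment_volume_L": self.config.compartment_volume,
            },
        }


def _theta_to_params(theta: np.ndarray, config: FitConfig) -> GatingParams:
    """Map a log-space free-parameter vector to a full, constrained set."""
    k_out = math.exp(theta[0])
    kwargs = dict(
        k_in=k_out * config.d_ratio,  # partition constraint, exact
        k_out=k_out,
        k_on=math.exp(theta[1]),
        k_off=math.exp(theta[2]),
        po_ratio=1.0 + math.exp(theta[3]),
        c_t=config.c_t,
    )
    if config.scheme.two_compartment:
        kwargs["k_flip"] = math.exp(theta[4])
    return GatingParams(**kwargs)


def _params_to_theta(guess: dict[str, float], config: FitConfig) -> np.ndarray:
    theta = [
        math.log(guess["k_out"]),
        math.log(guess["k_on"]),
        math.log(guess["k_off"]),
        math.log(guess["po_ratio"] - 1.0),
    ]
    if config.scheme.two_compartment:
        theta.append(math.log(guess["k_flip"]))
    return np.array(theta)


def ensemble_objective(
    params: GatingParams,
    traces: Sequence[ObservedTrace],
    config: FitConfig,
) -> float:
    """Sum of squared residuals of the scheme prediction over all traces.

    Each trace's protocol is integrated on the configured step and the
    prediction is linearly interpolated onto the trace's own time grid.
    Unweighted (plain) least squares.
    """
    if not traces:
        raise ValueError("trace set is empty")
    sse = 0.0
    for tr in traces:
        # record the simulation no denser than ~1 s (or the observed grid,
        # if finer): the relaxations are smooth on that scale and the
        # recording overhead is pure loss inside the optimizer
        obs_step = float(np.min(np.diff(tr.t)))
        rec = max(1, int(min(1.0, obs_step) / config.dt))
        sim = integrate_protocol(
            config.scheme, params, tr.protocol, dt=config.dt, record_every=rec
        )
        pred = np.interp(tr.t, sim.t, sim.i_norm)
        resid = pred - tr.i_norm
        sse += float(resid @ resid)
    return sse


def _default_guess(traces: Sequence[ObservedTrace], config: FitConfig) -> dict:
    strongest = max(traces, key=lambda tr: tr.protocol.max_conc)
    plateau = float(np.max(strongest.i_norm))
    guess = {
        "k_out": 0.1,
        "k_on": 1e3,
        "k_off": 0.01,
        "po_ratio": max(plateau, 1.0 + 1e-3),
    }
    if config.scheme.two_compartment:
        guess["k_flip"] = guess["k_out"]
    return guess


def fit_ensemble(
    traces: Sequence[ObservedTrace],
    config: FitConfig,
) -> FitResult:
    """Globally fit a scheme to a normalized trace ensemble.

    Downhill-simplex (Nelder-Mead) minimization of the ensemble sum of
    squared residuals over log-transformed free parameters, with ``k_in``
    tied to ``k_out`` through the partition constraint at every evaluation.
    If the first run fails to converge, one seeded restart is made from the
    best point with jittered coordinates.
    """
    if not traces:
        raise ValueError("trace set is empty")
    has_on = any(c > 0 for tr in traces for _, c in tr.protocol.segments)
    has_off = any(c == 0 for tr in traces for _, c in tr.protocol.segments)
    if not (has_on and has_off):
        import warnings

        warnings.warn(
            "ensemble lacks an on- or an off-relaxation; "
            "partition and dissociation rates may not be identifiable",
            stacklevel=2,
        )

    guess = dict(_default_guess(traces, config))
    if config.initial_guess:
        guess.update(config.initial_guess)
    theta0 = _params_to_theta(guess, config)

    def objective(theta: np.ndarray) -> float:
        try:
            return ensemble_objective(_theta_to_params(theta, config), traces, config)
        except (OverflowError, FloatingPointError):
            return np.inf

    def simplex_around(center: np.ndarray, spread: float) -> np.ndarray:
        # fixed absolute spread in log-parameter space: the default
        # value-proportional simplex degenerates when a log coordinate
        # happens to sit near zero
        vertices = np.tile(center, (center.size + 1, 1))
        for i in range(center.size):
            vertices[i + 1, i] += spread
        return vertices

    # restarted Nelder-Mead: a collapsed simplex can stall short of the
    # optimum (increasingly likely with five free parameters), so re-expand
    # a fresh simplex around the best point until the SSE stops improving
    rng = np.random.default_rng(config.seed)
    n_eval = 0
    remaining = config.max_evaluations
    theta, spread = theta0, 0.25
    best = None
    for _ in range(5):
        opts = dict(
            xatol=max(config.simplex_tolerance, 1e-6),
            fatol=config.simplex_tolerance,
            maxfev=remaining,
            initial_simplex=simplex_around(theta, spread),
        )
        res = minimize(objective, theta, method="Nelder-Mead", options=opts)
        n_eval += res.nfev
        remaining -= res.nfev
        improved = best is None or res.fun < best.fun * (1.0 - 1e-6)
        if best is None or res.fun < best.fun:
            best = res
        if remaining <= 100 or not improved:
            break
        # jittered re-expansion around the incumbent optimum
        theta = best.x + rng.normal(0.0, 0.01, size=best.x.size)
        spread = 0.1
    res = best

    params = _theta_to_params(res.x, config)
    return FitResult(
        params=params,
        sse=float(res.fun),
        derived=derived_affinities(config.scheme, params),
        converged=bool(res.success),
        n_evaluations=int(n_eval),
        scheme=config.scheme,
        config=config,
    )
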