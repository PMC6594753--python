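"""Compartmental drug-partition/binding gating models and their theory.

Four kinetic schemes describe reversible potentiation of an ion channel by a
highly lipophilic drug applied to the cytosolic face of an excised membrane
patch.  The drug partitions from the cytosolic bath into the membrane (rates
``k_in``, ``k_out``), optionally flips between the two membrane leaflets
(rate ``k_flip``), and binds to one or two independent sites on the channel
(rates ``k_on'``, ``k_off``).  Fully liganded channels gate with an open
probability elevated ``po_ratio``-fold above basal.

============  =====  ============  ==================================
scheme        sites  compartments  state vector x (concentrations, M)
============  =====  ============  ==================================
ONE_SITE        1     1            free membrane drug; unliganded channels
ONE_SITE_FLIP   1     2            inner-leaflet drug; outer-leaflet drug;
                                   unliganded channels
TWO_SITE        2     1            free membrane drug; unliganded channels;
                                   monoliganded channels
TWO_SITE_FLIP   2     2            inner-leaflet drug; outer-leaflet drug;
                                   unliganded channels; monoliganded channels
============  =====  ============  ==================================

Fully liganded channel concentration is carried implicitly as
``C_t - (sum of explicit channel states)``, so channel mass is conserved
exactly by construction.

The module provides the scheme right-hand sides, a fixed-step Heun
(predictor-corrector "modified Euler") integrator over piecewise-constant
drug application protocols, and the closed-form steady-state theory
(membrane drug concentrations, normalized steady current, derived apparent
affinities and midpoint Hill slope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Scheme",
    "GatingParams",
    "DrugProtocol",
    "SimulatedTrace",
    "IntegrationError",
    "rhs",
    "normalized_current",
    "initial_state",
    "integrate_protocol",
    "steady_state_concentrations",
    "steady_state_response",
    "derived_affinities",
    "saturated_conc",
    "midpoint_hill_slope",
]


class Scheme(IntEnum):
    """The four drug-partition/binding gating schemes.

    Numbering follows the conventional 2x2 layout: one or two drug binding
    sites, crossed with one or two membrane compartments (leaflets).
    """

    ONE_SITE = 1
    ONE_SITE_FLIP = 2
    TWO_SITE = 3
    TWO_SITE_FLIP = 4

    @property
    def n_sites(self) -> int:
        return 2 if self in (Scheme.TWO_SITE, Scheme.TWO_SITE_FLIP) else 1

    @property
    def two_compartment(self) -> bool:
        return self in (Scheme.ONE_SITE_FLIP, Scheme.TWO_SITE_FLIP)

    @property
    def n_states(self) -> int:
        return {1: 2, 2: 3, 3: 3, 4: 4}[int(self)]

    @property
    def unliganded_index(self) -> int:
        """Index of the unliganded-channel component in the state vector."""
        return 2 if self.two_compartment else 1


@dataclass(frozen=True)
class GatingParams:
    """Rate constants and open-probability ratio of a gating scheme.

    Parameters
    ----------
    k_in
        Drug entry rate into the membrane per unit cytosolic concentration
        (s^-1).
    k_out
        Drug exit rate from a membrane leaflet to the adjacent aqueous
        phase (s^-1).
    k_on
        Second-order binding rate of membrane-dissolved drug to a channel
        site (M^-1 s^-1).
    k_off
        Dissociation rate of bound drug (s^-1).
    po_ratio
        Ratio of fully-liganded to basal open probability,
        P_o;max / P_o;bas (>= 1).
    c_t
        Total channel-site concentration in the target compartment (M).
    k_flip
        Symmetric inter-leaflet flip-flop rate (s^-1); required by the
        two-compartment schemes, must be None otherwise.
    """

    k_in: float
    k_out: float
    k_on: float
    k_off: float
    po_ratio: float
    c_t: float
    k_flip: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_in", "k_out", "k_on", "k_off"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.po_ratio < 1:
            raise ValueError("po_ratio must be >= 1")
        if self.c_t <= 0:
            raise ValueError("c_t must be strictly positive")
        if self.k_flip is not None and self.k_flip <= 0:
            raise ValueError("k_flip, when present, must be strictly positive")

    def validate_for(self, scheme: Scheme) -> None:
        if scheme.two_compartment and self.k_flip is None:
            raise ValueError(f"{scheme.name} requires k_flip")
        if not scheme.two_compartment and self.k_flip is not None:
            raise ValueError(f"{scheme.name} does not take k_flip")


@dataclass(frozen=True)
class DrugProtocol:
    """Piecewise-constant cytosolic drug concentration profile.

    ``segments`` is an ordered list of ``(duration_s, conc_M)`` pairs.
    """

    segments: tuple[tuple[float, float], ...]

    def __init__(self, segments: Sequence[tuple[float, float]]):
        segs = tuple((float(d), float(c)) for d, c in segments)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        for d, c in segs:
            if d <= 0:
                raise ValueError("segment durations must be positive")
            if c < 0:
                raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "segments", segs)

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    @property
    def max_conc(self) -> float:
        return max(c for _, c in self.segments)

    @classmethod
    def on_off(cls, conc: float, t_on: float, t_off: float) -> "DrugProtocol":
        """Standard application/washout protocol: drug on, then wash."""
        return cls([(t_on, conc), (t_off, 0.0)])

    def to_json_obj(self) -> list[dict]:
        return [{"duration_s": d, "conc_M": c} for d, c in self.segments]

    @classmethod
    def from_json_obj(cls, obj: Sequence[dict]) -> "DrugProtocol":
        return cls([(seg["duration_s"], seg["conc_M"]) for seg in obj])


@dataclass
class SimulatedTrace:
    """Uniformly sampled normalized-current time course."""

    t: np.ndarray
    i_norm: np.ndarray
    protocol: DrugProtocol
    scheme: Scheme
    states: np.ndarray | None = field(default=None, repr=False)


class IntegrationError(RuntimeError):
    pass


# ----------------------------------------------------------------------------
# Right-hand sides.  The tuple-based private functions are the hot path of the
# ensemble fit; ``rhs`` is the array-based public face.

def _rhs1(x, vc, kin, kout, kon, koff, kflip, ct):
    x1, x2 = x
    bind = kon * x1 * x2
    unbind = koff * (ct - x2)
    return (kin * vc - 2.0 * kout * x1 - bind + unbind, -bind + unbind)


def _rhs2(x, vc, kin, kout, kon, koff, kflip, ct):
    x1, x2, x3 = x
    bind = kon * x2 * x3
    unbind = koff * (ct - x3)
    return (
        kin * vc - (kout + kflip) * x1 + kflip * x2,
        kflip * x1 - (kout + kflip) * x2 - bind + unbind,
        -bind + unbind,
    )


def _rhs3(x, vc, kin, kout, kon, koff, kflip, ct):
    x1, x2, x3 = x
    di = ct - x2 - x3  # diliganded channels, implicit
    return (
        kin * vc - 2.0 * kout * x1 - kon * (2.0 * x2 + x3) * x1
        + koff * (2.0 * di + x3),
        -2.0 * kon * x1 * x2 + koff * x3,
        2.0 * kon * x1 * x2 + 2.0 * koff * di - (koff + kon * x1) * x3,
    )


def _rhs4(x, vc, kin, kout, kon, koff, kflip, ct):
    x1, x2, x3, x4 = x
    di = ct - x3 - x4
    return (
        kin * vc - (kout + kflip) * x1 + kflip * x2,
        kflip * x1 - (kout + kflip) * x2 - kon * (2.0 * x3 + x4) * x2
        + koff * (2.0 * di + x4),
        -2.0 * kon * x2 * x3 + koff * x4,
        2.0 * kon * x2 * x3 + 2.0 * koff * di - (koff + kon * x2) * x4,
    )


_RHS: dict[Scheme, Callable] = {
    Scheme.ONE_SITE: _rhs1,
    Scheme.ONE_SITE_FLIP: _rhs2,
    Scheme.TWO_SITE: _rhs3,
    Scheme.TWO_SITE_FLIP: _rhs4,
}


def rhs(
    scheme: Scheme,
    params: GatingParams,
    state: Sequence[float],
    v_c: float,
) -> np.ndarray:
    """Time derivative dx/dt of the scheme's state vector.

    ``state`` components are compartment concentrations (M); ``v_c`` is the
    instantaneous cytosolic drug concentration (M).
    """
    params.validate_for(scheme)
    x = np.asarray(state, dtype=float)
    if x.shape != (scheme.n_states,):
        raise ValueError(
            f"{scheme.name} expects a state vector of length "
            f"{scheme.n_states}, got shape {x.shape}"
        )
    if np.any(x < 0):
        raise ValueError("state components must be non-negative")
    f = _RHS[scheme]
    kflip = params.k_flip if params.k_flip is not None else 0.0
    return np.array(
        f(tuple(x), v_c, params.k_in, params.k_out, params.k_on,
          params.k_off, kflip, params.c_t)
    )


def normalized_current(
    scheme: Scheme, params: GatingParams, state: Sequence[float]
) -> float:
    """Normalized current predicted from a state vector.

    The non-potentiated channel fraction (unliganded, plus monoliganded for
    the two-site schemes) contributes at the basal level 1; the remaining
    fully-liganded fraction contributes ``po_ratio``.
    """
    x = np.asarray(state, dtype=float)
    u = scheme.unliganded_index
    frac = x[u] / params.c_t
    if scheme.n_sites == 2:
        frac += x[u + 1] / params.c_t
    return float(frac + (1.0 - frac) * params.po_ratio)


def initial_state(scheme: Scheme, params: GatingParams) -> np.ndarray:
    """Pre-drug state: empty drug compartments, all channels unliganded.

    This makes the normalized current start exactly at 1, matching the
    normalization of experimental traces to their pre-drug steady state.
    """
    x = np.zeros(scheme.n_states)
    x[scheme.unliganded_index] = params.c_t
    return x


def _dt_cap(scheme: Scheme, params: GatingParams, protocol: DrugProtocol) -> float:
    """Largest step keeping the fixed-step integrator comfortably stable.

    Bounds the step by 0.1 over the fastest effective first-order rate:
    membrane exit, dissociation, flip-flop, and pseudo-first-order binding at
    the steady-state membrane drug concentration reached at the protocol's
    highest applied concentration.
    """
    vmax = protocol.max_conc
    if scheme.two_compartment:
        # upper bound on either leaflet's steady concentration
        v_m = vmax * params.k_in / params.k_out
    else:
        v_m = vmax * params.k_in / (2.0 * params.k_out)
    rates = [2.0 * params.k_out, params.k_off, params.k_on * v_m,
             params.k_on * 2.0 * params.c_t]
    if params.k_flip is not None:
        rates.append(2.0 * params.k_flip)
    return 0.1 / max(rates)


# Specialized Heun segment steppers.  These unroll the state into scalar
# locals: they are the hot path of the ensemble fit, where the generic
# tuple-based form costs a factor of several.  Tests assert they agree with
# the public ``rhs``-based generic step to round-off.

def _segment_s1(x, vc, h, n_steps, rec, kin, kout, kon, koff, kflip, ct,
                t0, times, fracs, states):
    x1, x2 = x
    half = 0.5 * h
    src = kin * vc
    t = t0
    for i in range(1, n_steps + 1):
        b = kon * x1 * x2
        u = koff * (ct - x2)
        d1a = src - 2.0 * kout * x1 - b + u
        d2a = -b + u
        p1 = x1 + h * d1a
        p2 = x2 + h * d2a
        b = kon * p1 * p2
        u = koff * (ct - p2)
        x1 += half * (d1a + src - 2.0 * kout * p1 - b + u)
        x2 += half * (d2a - b + u)
        t = t0 + i * h
        if i % rec == 0 or i == n_steps:
            times.append(t)
            fracs.append(x2 / ct)
            if states is not None:
                states.append((x1, x2))
    return (x1, x2), t


def _segment_s2(x, vc, h, n_steps, rec, kin, kout, kon, koff, kflip, ct,
                t0, times, fracs, states):
    x1, x2, x3 = x
    half = 0.5 * h
    src = kin * vc
    kk = kout + kflip
    t = t0
    for i in range(1, n_steps + 1):
        b = kon * x2 * x3
        u = koff * (ct - x3)
        d1 = src - kk * x1 + kflip * x2
        d2 = kflip * x1 - kk * x2 - b + u
        d3 = -b + u
        p1 = x1 + h * d1
        p2 = x2 + h * d2
        p3 = x3 + h * d3
        b = kon * p2 * p3
        u = koff * (ct - p3)
        x1 += half * (d1 + src - kk * p1 + kflip * p2)
        x2 += half * (d2 + kflip * p1 - kk * p2 - b + u)
        x3 += half * (d3 - b + u)
        t = t0 + i * h
        if i % rec == 0 or i == n_steps:
            times.append(t)
            fracs.append(x3 / ct)
            if states is not None:
                states.append((x1, x2, x3))
    return (x1, x2, x3), t


def _segment_s3(x, vc, h, n_steps, rec, kin, kout, kon, koff, kflip, ct,
                t0, times, fracs, states):
    x1, x2, x3 = x
    half = 0.5 * h
    src = kin * vc
    t = t0
    for i in range(1, n_steps + 1):
        di = ct - x2 - x3
        kx = kon * x1
        d1 = src - 2.0 * kout * x1 - kx * (2.0 * x2 + x3) \
            + koff * (2.0 * di + x3)
        d2 = -2.0 * kx * x2 + koff * x3
        d3 = 2.0 * kx * x2 + 2.0 * koff * di - (koff + kx) * x3
        p1 = x1 + h * d1
        p2 = x2 + h * d2
        p3 = x3 + h * d3
        di = ct - p2 - p3
        kx = kon * p1
        x1 += half * (d1 + src - 2.0 * kout * p1 - kx * (2.0 * p2 + p3)
                      + koff * (2.0 * di + p3))
        x2 += half * (d2 - 2.0 * kx * p2 + koff * p3)
        x3 += half * (d3 + 2.0 * kx * p2 + 2.0 * koff * di - (koff + kx) * p3)
        t = t0 + i * h
        if i % rec == 0 or i == n_steps:
            times.append(t)
            fracs.append((x2 + x3) / ct)
            if states is not None:
                states.append((x1, x2, x3))
    return (x1, x2, x3), t


def _segment_s4(x, vc, h, n_steps, rec, kin, kout, kon, koff, kflip, ct,
                t0, times, fracs, states):
    x1, x2, x3, x4 = x
    half = 0.5 * h
    src = kin * vc
    kk = kout + kflip
    t = t0
    for i in range(1, n_steps + 1):
        di = ct - x3 - x4
        kx = kon * x2
        d1 = src - kk * x1 + kflip * x2
        d2 = kflip * x1 - kk * x2 - kx * (2.0 * x3 + x4) \
            + koff * (2.0 * di + x4)
        d3 = -2.0 * kx * x3 + koff * x4
        d4 = 2.0 * kx * x3 + 2.0 * koff * di - (koff + kx) * x4
        p1 = x1 + h * d1
        p2 = x2 + h * d2
        p3 = x3 + h * d3
        p4 = x4 + h * d4
        di = ct - p3 - p4
        kx = kon * p2
        x1 += half * (d1 + src - kk * p1 + kflip * p2)
        x2 += half * (d2 + kflip * p1 - kk * p2 - kx * (2.0 * p3 + p4)
                      + koff * (2.0 * di + p4))
        x3 += half * (d3 - 2.0 * kx * p3 + koff * p4)
        x4 += half * (d4 + 2.0 * kx * p3 + 2.0 * koff * di - (koff + kx) * p4)
        t = t0 + i * h
        if i % rec == 0 or i == n_steps:
            times.append(t)
            fracs.append((x3 + x4) / ct)
            if states is not None:
                states.append((x1, x2, x3, x4))
    return (x1, x2, x3, x4), t


_SEGMENT: dict[Scheme, Callable] = {
    Scheme.ONE_SITE: _segment_s1,
    Scheme.ONE_SITE_FLIP: _segment_s2,
    Scheme.TWO_SITE: _segment_s3,
    Scheme.TWO_SITE_FLIP: _segment_s4,
}


def integrate_protocol(
    scheme: Scheme,
    params: GatingParams,
    protocol: DrugProtocol,
    dt: float = 0.01,
    record_every: int = 1,
    keep_states: bool = False,
) -> SimulatedTrace:
    """Integrate a scheme over a drug protocol with Heun's method.

    The requested step ``dt`` is reduced automatically if the parameter set
    demands a smaller stable step (see :func:`_dt_cap`); within each protocol
    segment the step is then rounded down so the segment boundary falls
    exactly on the grid, and the state is carried continuously across
    boundaries.  Every ``record_every``-th step is recorded.

    Raises
    ------
    IntegrationError
        If any state component falls below ``-1e-9 * c_t`` (instability),
        naming the offending time.
    """
    params.validate_for(scheme)
    if dt <= 0:
        raise ValueError("dt must be positive")
    dt_eff = min(dt, _dt_cap(scheme, params, protocol))

    stepper = _SEGMENT[scheme]
    kin, kout, kon, koff = params.k_in, params.k_out, params.k_on, params.k_off
    kflip = params.k_flip if params.k_flip is not None else 0.0
    ct = params.c_t
    neg_tol = -1e-9 * ct

    x = tuple(initial_state(scheme, params))
    u = scheme.unliganded_index
    two_site = scheme.n_sites == 2
    frac0 = (x[u] + (x[u + 1] if two_site else 0.0)) / ct
    times: list[float] = [0.0]
    fracs: list[float] = [frac0]
    states: list[tuple] | None = [x] if keep_states else None

    t_abs = 0.0
    for duration, vc in protocol.segments:
        n_steps = max(1, math.ceil(duration / dt_eff))
        h = duration / n_steps
        x, t_abs = stepper(x, vc, h, n_steps, record_every, kin, kout, kon,
                           koff, kflip, ct, t_abs, times, fracs, states)
        if min(x) < neg_tol or not all(math.isfinite(v) for v in x):
            raise IntegrationError(
                f"integration unstable near t = {t_abs:.6g} s "
                f"(state {x}); reduce dt"
            )
        x = tuple(v if v > 0.0 else 0.0 for v in x)

    frac_arr = np.array(fracs)
    i_norm = frac_arr + (1.0 - frac_arr) * params.po_ratio
    return SimulatedTrace(
        t=np.array(times),
        i_norm=i_norm,
        protocol=protocol,
        scheme=scheme,
        states=np.array(states) if keep_states else None,
    )


# ----------------------------------------------------------------------------
# Closed-form steady-state theory.

def steady_state_concentrations(
    scheme: Scheme, params: GatingParams, v_c: float
) -> float | tuple[float, float]:
    """Steady-state membrane drug concentration(s) at cytosolic level v_c.

    Single-compartment schemes return the membrane concentration
    ``V_m;inf = v_c * k_in / (2 k_out)``.  Two-leaflet schemes return the
    ``(cytosolic-leaflet, external-leaflet)`` pair, which accounts for the
    steady outward drug flux through the membrane into the (effectively
    infinite) pipette solution.
    """
    params.validate_for(scheme)
    if not scheme.two_compartment:
        return v_c * params.k_in / (2.0 * params.k_out)
    ko, kf = params.k_out, params.k_flip
    ratio = params.k_in / ko
    v_mc = v_c * ratio * (ko + kf) / (ko + 2.0 * kf)
    v_me = v_c * ratio * kf / (ko + 2.0 * kf)
    return v_mc, v_me


def steady_state_response(
    scheme: Scheme, params: GatingParams, v_c: float
) -> float:
    """Normalized steady-state current at cytosolic drug concentration v_c.

    The channel pool equilibrates with the drug concentration in its target
    compartment ``V_inf``; the potentiated fraction is the monoliganded
    occupancy ``Y1 = V/(Kd+V)`` for one-site schemes or the diliganded
    occupancy ``Y2 = (V/(Kd+V))^2`` for two-site schemes, with
    ``Kd = k_off/k_on'``.
    """
    conc = steady_state_concentrations(scheme, params, v_c)
    v_inf = conc[1] if scheme.two_compartment else conc
    kd = params.k_off / params.k_on
    y1 = v_inf / (kd + v_inf) if v_inf > 0 else 0.0
    y = y1 ** scheme.n_sites
    return 1.0 + (params.po_ratio - 1.0) * y


def derived_affinities(
    scheme: Scheme, params: GatingParams
) -> tuple[float, float, float]:
    """Apparent affinities ``(K_d;mem, K_0.5;mem, K_0.5;aq)`` in M.

    ``K_d;mem`` is the intramembrane dissociation constant ``k_off/k_on'``;
    ``K_0.5;mem`` the intramembrane concentration giving half-maximal
    stimulation (``(1+sqrt(2)) * K_d;mem`` for the two-site schemes, where
    half-maximal diliganded occupancy requires Y1 = 1/sqrt(2)); and
    ``K_0.5;aq`` the corresponding aqueous (cytosolic) concentration, scaled
    by the steady-state membrane accumulation factor.
    """
    params.validate_for(scheme)
    kd_mem = params.k_off / params.k_on
    k05_mem = kd_mem * (1.0 + math.sqrt(2.0)) if scheme.n_sites == 2 else kd_mem
    if scheme.two_compartment:
        ko, kf = params.k_out, params.k_flip
        accumulation = (params.k_in / ko) * kf / (ko + 2.0 * kf)
    else:
        accumulation = params.k_in / (2.0 * params.k_out)
    return kd_mem, k05_mem, k05_mem / accumulation


def saturated_conc(x: float, calibration: float = None) -> float:
    """Aqueous concentration (M) of an x-fold dilution of a saturated stock.

    ``calibration`` is the solubility assigned to the 1x stock; defaults to
    the package-wide 62 nM convention.
    """
    from .constants import SATURATED_CONC

    if x < 0:
        raise ValueError("dilution multiple must be non-negative")
    return x * (SATURATED_CONC if calibration is None else calibration)


def midpoint_hill_slope(scheme: Scheme) -> float:
    """Logit slope of the steady-state dose-response curve at its midpoint.

    One-site occupancy gives a true Hill slope of 1.  For the two-site
    schemes the diliganded-occupancy curve Y2 has midpoint logit slope
    ``2 * (2 - sqrt(2)) ~ 1.17`` -- well below the naive value 2, because the
    two sites fill independently.
    """
    if scheme.n_sites == 2:
        return 2.0 * (2.0 - math.sqrt(2.0))
    return 1.0
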