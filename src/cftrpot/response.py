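"""Empirical analysis of macroscopic current responses.

Model-free summaries of drug application experiments: fractional steady
stimulation, Hill dose-response fitting, single-exponential deactivation
after washout, an empirical irreversible three-step activation chain for the
sigmoidal onset, and the apparent activation time constant tau_on*.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponsePoint",
    "HillFitResult",
    "ExpDecayFit",
    "ThreeStepFit",
    "fractional_stimulation",
    "hill_curve",
    "fit_hill",
    "fit_exponential_decay",
    "three_step_occupancy",
    "fit_three_step_activation",
    "tau_on_star",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DoseResponsePoint:
    """One dose-response observation: fractional stimulation at a
    cytosolic drug concentration (M)."""

    conc: float
    stimulation: float
    sem: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class HillFitResult:
    """Parameters of the modified Hill equation
    ``I/I_ctrl = (K^n + R c^n) / (K^n + c^n)``, which rises from 1 at
    c = 0 to the maximal fold-stimulation R as c -> inf."""

    k05: float
    n_hill: float
    imax_ratio: float
    residual_sse: float


@dataclass
class ExpDecayFit:
    tau: float
    amplitude: float
    offset: float
    residual_sse: float
    flagged: bool = False

    @property
    def rate(self) -> float:
        """Deactivation rate 1/tau_off (s^-1)."""
        return 1.0 / self.tau


@dataclass
class ThreeStepFit:
    """Empirical irreversible chain S1 -> S2 -> S3 -> S4 fitted to a
    sigmoidal activation time course; channels gate at the basal level in
    S1-S3 and at ``po_s4_ratio``-fold stimulation in S4."""

    k12: float
    k23: float
    k34: float
    po_s4_ratio: float
    tau_on_star: float
    residual_sse: float


def _window_mean(t: np.ndarray, y: np.ndarray, window: tuple[float, float]) -> float:
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] contains no samples")
    return float(y[mask].mean())


def fractional_stimulation(
    t: np.ndarray,
    current: np.ndarray,
    pre_window: tuple[float, float],
    drug_window: tuple[float, float],
    post_window: tuple[float, float],
) -> float:
    """Fold-stimulation I/I_control of the steady drug-on current.

    The steady current in the drug is referenced to the average of the pre-
    and post-drug steady currents, which corrects for slow monotonic rundown.
    """
    t = np.asarray(t, dtype=float)
    current = np.asarray(current, dtype=float)
    windows = [pre_window, drug_window, post_window]
    for (a, b), (c, d) in zip(windows, windows[1:]):
        if b > c:
            raise ValueError("windows must be disjoint and ordered")
    pre = _window_mean(t, current, pre_window)
    drug = _window_mean(t, current, drug_window)
    post = _window_mean(t, current, post_window)
    denom = 0.5 * (pre + post)
    if denom == 0:
        raise ValueError("pre/post mean current is zero")
    return drug / denom


def hill_curve(conc, k05: float, n_hill: float, imax_ratio: float):
    """Modified Hill equation; equals 1 at c = 0, imax_ratio at saturation,
    and ``(1 + imax_ratio)/2`` at c = k05."""
    c = np.asarray(conc, dtype=float)
    cn = (c / k05) ** n_hill
    return (1.0 + imax_ratio * cn) / (1.0 + cn)


def fit_hill(points: Sequence[DoseResponsePoint]) -> HillFitResult:
    """Least-squares fit of the modified Hill equation to dose-response data.

    K_0.5 is optimized on a log10 scale; residuals are unweighted in
    stimulation units.  At least 4 points spanning at least a decade, with
    data on both sides of the midpoint, are needed for a well-conditioned
    fit (a warning is issued otherwise).
    """
    pts = [p for p in points if p.conc > 0]
    if len(pts) < 3:
        raise ValueError("need at least 3 points at non-zero concentration")
    conc = np.array([p.conc for p in pts])
    stim = np.array([p.stimulation for p in pts])
    if np.allclose(stim, stim[0]):
        raise ValueError("degenerate dose-response data: all stimulations equal")
    span = conc.max() / conc.min()
    if len(pts) < 4 or span < 10:
        warnings.warn(
            "fewer than 4 points or less than one decade of concentrations; "
            "Hill parameters may be poorly constrained",
            stacklevel=2,
        )

    r0 = max(stim.max(), 1.0 + 1e-6)
    half = (1.0 + r0) / 2.0
    k0 = conc[np.argmin(np.abs(stim - half))]

    def resid(theta):
        logk, n, r = theta
        return hill_curve(conc, 10.0**logk, n, r) - stim

    sol = least_squares(
        resid,
        x0=[math.log10(k0), 1.0, r0],
        bounds=([-15.0, 0.05, 1.0], [0.0, 10.0, 1e4]),
    )
    logk, n, r = sol.x
    sse = float(sol.fun @ sol.fun)
    mid_covered = (conc.min() < 10.0**logk < conc.max())
    if not mid_covered:
        warnings.warn("fitted midpoint lies outside the sampled range", stacklevel=2)
    return HillFitResult(k05=10.0**logk, n_hill=float(n), imax_ratio=float(r),
                         residual_sse=sse)


def fit_exponential_decay(t: np.ndarray, y: np.ndarray) -> ExpDecayFit:
    """Single-exponential fit ``a + b exp(-t/tau)`` to a washout segment.

    ``t`` is measured from drug removal.  The free offset ``a`` is the
    post-drug level the current relaxes back to.  A non-decaying segment is
    returned flagged rather than raising.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 20:
        raise ValueError("need at least 20 samples for a decay fit")
    t = t - t[0]

    a0 = float(y[-max(3, t.size // 10):].mean())
    b0 = float(y[0] - a0)
    span = t[-1] - t[0]
    if b0 <= 0 or np.ptp(y) < 1e-12:
        return ExpDecayFit(tau=span, amplitude=max(b0, 0.0), offset=a0,
                           residual_sse=float(np.var(y) * y.size), flagged=True)

    def resid(theta):
        a, b, logtau = theta
        return a + b * np.exp(-t / math.exp(logtau)) - y

    sol = least_squares(resid, x0=[a0, b0, math.log(max(span / 3.0, 1e-6))])
    a, b, logtau = sol.x
    tau = math.exp(logtau)
    flagged = (b <= 0) or (tau > 50.0 * span)
    return ExpDecayFit(tau=float(tau), amplitude=float(b), offset=float(a),
                       residual_sse=float(sol.fun @ sol.fun), flagged=flagged)


# ----------------------------------------------------------------------------
# Irreversible three-step chain.

def three_step_occupancy(t, k12: float, k23: float, k34: float):
    """Occupancy of the terminal state S4 of the chain S1->S2->S3->S4.

    Closed-form hypoexponential CDF: P(S4, t) = P(X1 + X2 + X3 <= t) with
    independent exponential step times.  Branches handle coincident rates
    (within 1e-6 relative) exactly instead of numerically cancelling.
    """
    t = np.asarray(t, dtype=float)
    rates = sorted([k12, k23, k34])
    if min(rates) <= 0:
        raise ValueError("chain rates must be positive")

    def close(a, b):
        return abs(a - b) <= 1e-6 * max(a, b)

    l1, l2, l3 = rates
    if close(l1, l2) and close(l2, l3):
        lam = (l1 + l2 + l3) / 3.0
        x = lam * t
        return 1.0 - np.exp(-x) * (1.0 + x + 0.5 * x * x)
    if close(l1, l2) or close(l2, l3) or close(l1, l3):
        if close(l1, l2):
            lam, m = 0.5 * (l1 + l2), l3
        elif close(l2, l3):
            lam, m = 0.5 * (l2 + l3), l1
        else:
            lam, m = 0.5 * (l1 + l3), l2
        a = lam - m
        g = lam / a
        return (1.0 - np.exp(-lam * t) * (1.0 + lam * t)
                - g * g * (np.exp(-m * t) - np.exp(-lam * t) * (1.0 + a * t)))
    total = 1.0
    for li in rates:
        coeff = 1.0
        for lj in rates:
            if lj != li:
                coeff *= lj / (lj - li)
        total = total - coeff * np.exp(-li * t)
    return total


def fit_three_step_activation(
    t: np.ndarray,
    i_norm: np.ndarray,
    po_s4_ratio: float | None = None,
) -> ThreeStepFit:
    """Fit the empirical three-step chain to a normalized activation onset.

    The predicted normalized current is ``1 + (R - 1) * P(S4, t)`` where R is
    the fold-stimulation of the terminal compound state; the basal level of
    the first three states is fixed at 1 (the normalized pre-drug current).
    If ``po_s4_ratio`` is given it is held fixed; otherwise it is free.
    tau_on* of the fitted curve is reported alongside the rates.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(i_norm, dtype=float)
    if t.size < 3:
        raise ValueError("segment too short for a three-step fit")
    tt = t - t[0]
    plateau = float(y[-max(3, y.size // 10):].mean())
    r0 = po_s4_ratio if po_s4_ratio is not None else max(plateau, 1.0 + 1e-3)
    # crude scale: time to half-rise
    half = 0.5 * (y[0] + plateau)
    above = np.nonzero(y >= half)[0]
    t_half = tt[above[0]] if above.size else tt[-1] / 2.0
    k0 = 3.0 / max(t_half, tt[-1] / 100.0)

    fixed_r = po_s4_ratio is not None

    def model(theta):
        k12, k23, k34 = np.exp(theta[:3])
        r = r0 if fixed_r else 1.0 + math.exp(theta[3])
        return 1.0 + (r - 1.0) * three_step_occupancy(tt, k12, k23, k34)

    def resid(theta):
        return model(theta) - y

    x0 = [math.log(k0), math.log(k0 / 2.0), math.log(k0 / 4.0)]
    if not fixed_r:
        x0.append(math.log(max(r0 - 1.0, 1e-6)))
    sol = least_squares(resid, x0=np.array(x0), xtol=1e-12, ftol=1e-12)
    k12, k23, k34 = (float(v) for v in np.exp(sol.x[:3]))
    r = r0 if fixed_r else 1.0 + math.exp(sol.x[3])
    fit_curve = model(sol.x)
    try:
        tstar = tau_on_star(tt, fit_curve)
    except ValueError:
        tstar = float("nan")
    return ThreeStepFit(k12=k12, k23=k23, k34=k34, po_s4_ratio=float(r),
                        tau_on_star=tstar,
                        residual_sse=float(sol.fun @ sol.fun))


def tau_on_star(t: np.ndarray, y: np.ndarray) -> float:
    """Apparent activation time constant tau_on* = T_1/2 / ln 2.

    T_1/2 is the first time the trace crosses the midpoint between its
    initial and fully-activated (plateau) amplitudes; the plateau is the
    mean of the final 10% of samples, which must be stable (each within 2%
    of their mean).  For a pure exponential rise this definition returns the
    true time constant exactly.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tail = y[-max(2, y.size // 10):]
    plateau = float(tail.mean())
    if np.any(np.abs(tail - plateau) > 0.02 * abs(plateau)):
        raise ValueError("no stable plateau: final 10% of samples vary by > 2%")
    pre = float(y[0])
    half = 0.5 * (pre + plateau)
    tt = t - t[0]
    above = np.nonzero(y >= half)[0] if plateau >= pre else np.nonzero(y <= half)[0]
    if above.size == 0 or above[0] == 0:
        if above.size and above[0] == 0:
            return 0.0
        raise ValueError("trace never crosses its half-activation level")
    i = above[0]
    # linear interpolation across the crossing sample pair
    t_half = tt[i - 1] + (half - y[i - 1]) / (y[i] - y[i - 1]) * (tt[i] - tt[i - 1])
    return float(t_half / LN2)
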