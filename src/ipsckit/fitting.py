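"""Mono- and biexponential decay fitting and the weighted time constant.

The decay of an IPSC is modeled as a sum of one or two exponentials,
``y(t) = sum_i A_i exp(-t/tau_i)``, fitted by least squares from the peak.
For dual fits the amplitude-weighted time constant

    tau_w = (tau1*A1 + tau2*A2) / (A1 + A2)

summarizes the decay in a single number.  Model order (one vs two
exponentials) is chosen by an extra-sum-of-squares F-test at a strict
significance level.

Implementation notes: the nonlinear search runs over log time constants
only; for any candidate taus the amplitudes are solved exactly by
non-negative linear least squares (variable projection), which makes the
fit fast and insensitive to amplitude initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.stats import f as f_dist

from .errors import FitConvergenceError
from .trace import Trace

__all__ = ["DecayFit", "fit_exponential", "tau_w", "select_n_exponentials"]


@dataclass
class DecayFit:
    """Exponential-decay fit result; components sorted by ascending tau."""

    components: List[Tuple[float, float]]   # (amplitude pA, tau ms)
    sse: float
    dof: int
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: c[1])

    @property
    def n(self) -> int:
        return len(self.components)

    @property
    def tau_w(self) -> float:
        return tau_w(self)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum(a * np.exp(-t / tau) for a, tau in self.components)


def tau_w(fit: DecayFit) -> float:
    """Amplitude-weighted mean of the component time constants (ms)."""
    amps = np.array([a for a, _ in fit.components])
    taus = np.array([tau for _, tau in fit.components])
    total = amps.sum()
    if total <= 0:
        raise ValueError("cannot weight time constants: total amplitude is zero")
    return float(np.dot(amps, taus) / total)


def _as_y_dt(segment: Union[Trace, np.ndarray, Sequence[float]], dt: Optional[float]) -> Tuple[np.ndarray, float]:
    if isinstance(segment, Trace):
        return np.asarray(segment.samples, dtype=float), segment.dt
    if dt is None:
        raise ValueError("dt must be given when the segment is a bare array")
    return np.asarray(segment, dtype=float), dt


def fit_exponential(
    segment: Union[Trace, np.ndarray, Sequence[float]],
    n: int = 1,
    init: Optional[Sequence[float]] = None,
    dt: Optional[float] = None,
) -> DecayFit:
    """Least-squares fit of ``sum_i A_i exp(-t/tau_i)`` to a decay segment.

    The segment must start at the peak (positive-going; pass magnitudes)
    and contain at least 20 samples.  ``init`` optionally gives starting
    time constants in ms; otherwise deterministic defaults are used
    (tau at 10% and 60% of the segment length, plus a second faster start
    at 2% and 20%, keeping the better of the two).  Amplitudes are solved
    by non-negative linear least squares at every step.

    Time constants collapsing onto the search bounds, or components whose
    amplitude vanishes, are flagged (``"tau_at_bound"``,
    ``"amplitude_collapsed"``); a fit that cannot converge raises
    :class:`FitConvergenceError`.
    """
    y, dt = _as_y_dt(segment, dt)
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    if y.size < 20:
        raise ValueError("decay segment must contain at least 20 samples")
    t = dt * np.arange(y.size)
    T = t[-1]
    scale = float(np.max(np.abs(y)))
    if scale == 0:
        raise FitConvergenceError("segment is identically zero")

    lo_tau, hi_tau = dt / 2.0, 20.0 * T
    log_lo, log_hi = np.log(lo_tau), np.log(hi_tau)

    def amps_for(taus: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        basis = np.exp(-t[:, None] / taus[None, :])
        a, _ = nnls(basis, y)
        return a, basis

    def residuals(log_taus: np.ndarray) -> np.ndarray:
        a, basis = amps_for(np.exp(log_taus))
        return basis @ a - y

    if init is not None:
        starts = [np.asarray(init, dtype=float)]
        if len(starts[0]) != n:
            raise ValueError("init must supply one tau per component")
    elif n == 1:
        starts = [np.array([0.3 * T]), np.array([0.05 * T])]
    else:
        starts = [np.array([0.10 * T, 0.60 * T]), np.array([0.02 * T, 0.20 * T])]

    best = None
    for tau0 in starts:
        x0 = np.clip(np.log(tau0), log_lo + 1e-9, log_hi - 1e-9)
        res = least_squares(
            residuals, x0, bounds=(log_lo, log_hi), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
        )
        if res.status <= 0:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitConvergenceError(f"exponential fit did not converge (n={n})")

    taus = np.exp(best.x)
    amps, basis = amps_for(taus)
    sse = float(np.sum((basis @ amps - y) ** 2))

    flags: List[str] = []
    if np.any(best.x <= log_lo + 1e-3) or np.any(best.x >= log_hi - 1e-3):
        flags.append("tau_at_bound")
    if np.any(amps <= 1e-6 * scale):
        flags.append("amplitude_collapsed")
    if n == 2 and abs(np.log(taus[0] / taus[1])) < 1e-3:
        flags.append("tau_degenerate")

    fit = DecayFit(
        components=[(float(a), float(tau)) for a, tau in zip(amps, taus)],
        sse=sse,
        dof=y.size - 2 * n,
        flags=flags,
    )
    return fit


def select_n_exponentials(
    segment: Union[Trace, np.ndarray, Sequence[float]],
    alpha: float = 1e-4,
    dt: Optional[float] = None,
) -> DecayFit:
    """Fit one and two exponentials; keep the second only if warranted.

    The comparison is the extra-sum-of-squares F-test
    ``F = ((SSE1 - SSE2)/2) / (SSE2/dof2)`` with df = (2, dof2), accepted
    at significance ``alpha``.  A two-exponential fit that fails to
    converge, collapses, or does not reduce the error falls back to the
    monoexponential.
    """
    y, dt = _as_y_dt(segment, dt)
    fit1 = fit_exponential(y, n=1, dt=dt)
    try:
        fit2 = fit_exponential(y, n=2, dt=dt)
    except FitConvergenceError:
        return fit1
    if "amplitude_collapsed" in fit2.flags or "tau_degenerate" in fit2.flags:
        return fit1
    if fit2.sse >= fit1.sse:
        return fit1
    scale2 = float(np.sum(y ** 2))
    if fit1.sse - fit2.sse <= 1e-12 * scale2:
        # both fits already at numerical noise; extra component unsupported
        return fit1
    if fit2.sse <= 1e-20 * scale2:
        return fit2  # essentially exact two-exponential data
    F = ((fit1.sse - fit2.sse) / 2.0) / (fit2.sse / fit2.dof)
    p = float(f_dist.sf(F, 2, fit2.dof))
    return fit2 if p < alpha else fit1
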