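"""Lag-phase progress-curve fitting and Michaelis-Menten analysis.

Raw absorbance traces (A340 falls as cofactor is consumed) are negated
and zeroed at the window start so the fitted quantity increases like the
product concentration; the lag model is
``y(t) = V*t + A*(exp(-lam*t) - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import FitConvergenceError
from .kinetics import lag_progress_model

__all__ = [
    "ProgressCurve",
    "ProgressFit",
    "MMFit",
    "select_fit_window",
    "fit_progress_curve",
    "residual_randomness",
    "fit_michaelis_menten",
]

MIN_CURVE_POINTS = 10

#: Default A340 change per molar of cofactor consumed (delta-epsilon at
#: 340 nm times an effective plate pathlength), AU / M.  Configurable.
DEFAULT_EXTINCTION_PATH = 6220.0 * 0.5


@dataclass
class ProgressCurve:
    """A time series of optical signal at known assay concentrations.

    Parameters
    ----------
    times : ndarray
        Seconds, strictly increasing, >= 10 points.
    signal : ndarray
        Absorbance at 340 nm (AU); same length as ``times``.
    substrate_conc, cofactor_conc, enzyme_conc : float
        Molar concentrations of DHF, NADPH and enzyme (NaN if unknown).
    """

    times: np.ndarray
    signal: np.ndarray
    substrate_conc: float = float("nan")
    cofactor_conc: float = float("nan")
    enzyme_conc: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.signal.shape:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if len(self.times) < MIN_CURVE_POINTS:
            raise ValueError(f"progress curve needs >= {MIN_CURVE_POINTS} points, got {len(self.times)}")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.signal))):
            raise ValueError("times and signal must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ProgressFit:
    """Estimates of (V, A, lam) for one progress curve."""

    V: float
    A: float
    lam: float
    V_err: float
    A_err: float
    lam_err: float
    window: slice
    residuals: np.ndarray
    reduced_chi2: float
    lag_detected: bool
    degenerate: bool = False
    message: str = ""


@dataclass
class MMFit:
    """Michaelis-Menten fit of steady-state velocities."""

    Vmax: float
    Km: float
    Vmax_err: float
    Km_err: float
    residuals: np.ndarray
    identifiable: bool
    flags: list = field(default_factory=list)


def select_fit_window(
    curve: ProgressCurve,
    depletion_fraction: float = 0.10,
    extinction_path: float = DEFAULT_EXTINCTION_PATH,
) -> slice:
    """Longest prefix over which substrate consumption stays small.

    The cumulative signal change is compared against the stoichiometric
    maximum ``substrate_conc * extinction_path``; the window ends where
    consumption first exceeds ``depletion_fraction`` of it (never shorter
    than 10 points).  If the substrate concentration is unknown the full
    range is returned.
    """
    if not (0 < depletion_fraction < 1):
        raise ValueError("depletion_fraction must lie in (0, 1)")
    n = len(curve)
    if n < MIN_CURVE_POINTS:
        raise ValueError("curve too short for window selection")
    if not (math.isfinite(curve.substrate_conc) and curve.substrate_conc > 0):
        return slice(0, n)
    limit = depletion_fraction * curve.substrate_conc * extinction_path
    consumed = np.abs(curve.signal - curve.signal[0])
    over = np.nonzero(consumed > limit)[0]
    stop = n if len(over) == 0 else int(over[0])
    return slice(0, max(stop, MIN_CURVE_POINTS))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # deterministic, data-driven: V from the last third's slope, A from the
    # asymptote intercept, lam from the half-decay of the lag deficit
    n = len(t)
    tail = slice(max(0, 2 * n // 3), n)
    V0, c0 = np.polyfit(t[tail], y[tail], 1)
    A0 = max(-c0, 0.0)
    span = t[-1] - t[0]
    lam0 = 5.0 / span
    if A0 > 0:
        deficit = y - (V0 * t - A0)  # equals A*exp(-lam*t) under the model
        below = np.nonzero(deficit <= A0 / 2)[0]
        if len(below) and t[below[0]] > 0:
            lam0 = math.log(2.0) / t[below[0]]
    return float(V0), float(A0), float(lam0)


def fit_progress_curve(
    curve: ProgressCurve,
    window: slice | None = None,
    sigma: float | np.ndarray | None = None,
    orientation: str = "auto",
) -> ProgressFit:
    """Least-squares fit of the lag model to one progress curve.

    Parameters
    ----------
    curve : ProgressCurve
    window : slice, optional
        Index range to fit (default: the whole curve; see
        :func:`select_fit_window`).
    sigma : float or ndarray, optional
        Known noise level of the signal; when given, ``reduced_chi2`` is
        an absolute goodness-of-fit statistic.
    orientation : {"auto", "decreasing", "increasing"}
        "decreasing" negates the signal (A340-style raw data);
        "auto" negates only if the overall trend is downward.

    Returns
    -------
    ProgressFit
        With ``lag_detected = |A| > 2 * A_err``.  Non-convergence raises
        :class:`FitConvergenceError`; a rank-deficient covariance (e.g. a
        lag-free curve, where ``lam`` is unidentifiable) is flagged
        ``degenerate`` with infinite errors, never silently hidden.
    """
    if window is None:
        window = slice(0, len(curve))
    t_raw = curve.times[window]
    y_raw = curve.signal[window]
    if len(t_raw) < MIN_CURVE_POINTS:
        raise ValueError("fit window shorter than 10 points")

    if orientation not in ("auto", "decreasing", "increasing"):
        raise ValueError(f"unknown orientation {orientation!r}")
    flip = orientation == "decreasing" or (
        orientation == "auto" and y_raw[-1] < y_raw[0]
    )
    t = t_raw - t_raw[0]
    y = (y_raw[0] - y_raw) if flip else (y_raw - y_raw[0])

    p0 = _initial_guess(t, y)
    sigma_arr = None
    if sigma is not None:
        sigma_arr = np.broadcast_to(np.asarray(sigma, dtype=float), y.shape)
    try:
        popt, pcov = optimize.curve_fit(
            lag_progress_model,
            t,
            y,
            p0=p0,
            sigma=sigma_arr,
            absolute_sigma=sigma_arr is not None,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            x_scale=[max(abs(p0[0]), 1e-12), max(abs(p0[1]), 1e-9), max(p0[2], 1e-9)],
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
            maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - depends on optimizer
        raise FitConvergenceError(
            f"progress-curve fit did not converge (p0={p0}): {exc}"
        ) from exc

    V, A, lam = (float(v) for v in popt)
    perr = np.sqrt(np.abs(np.diag(pcov)))
    degenerate = bool(not np.all(np.isfinite(perr)))
    message = ""
    if degenerate:
        message = "covariance rank-deficient; lag parameters unidentifiable"
    span = t[-1] - t[0]
    dt_med = float(np.median(np.diff(t)))
    if lam * span < 1e-8 or not math.isfinite(lam):
        degenerate = True
        message = (message + "; " if message else "") + "lam at bound"
    # a "lag" faster than the sampling interval is an unresolved offset,
    # not an observable lag phase
    lag_resolved = lam * dt_med < 1.0
    if not lag_resolved:
        message = (message + "; " if message else "") + "lag faster than sampling interval"

    residuals = y - lag_progress_model(t, V, A, lam)
    dof = max(len(y) - 3, 1)
    if sigma_arr is not None:
        reduced_chi2 = float(np.sum((residuals / sigma_arr) ** 2) / dof)
    else:
        reduced_chi2 = float(np.sum(residuals**2) / dof)

    A_err = float(perr[1])
    lag_detected = bool(math.isfinite(A_err) and abs(A) > 2 * A_err and lag_resolved)
    return ProgressFit(
        V=V,
        A=A,
        lam=lam,
        V_err=float(perr[0]),
        A_err=A_err,
        lam_err=float(perr[2]),
        window=window,
        residuals=residuals,
        reduced_chi2=reduced_chi2,
        lag_detected=lag_detected,
        degenerate=degenerate,
        message=message,
    )


def residual_randomness(fit, alpha: float = 0.05) -> dict:
    """Wald-Wolfowitz runs test on the signs of the fit residuals.

    Accepts a :class:`ProgressFit` or a bare residual array (>= 20
    non-zero entries).  Returns ``statistic`` (the normal-approximation
    z), ``p_value``, ``runs`` and ``passed`` (two-sided p >= ``alpha``).
    """
    residuals = fit.residuals if isinstance(fit, ProgressFit) else np.asarray(fit, float)
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    if len(signs) < 20:
        raise ValueError(f"need >= 20 non-zero residuals, got {len(signs)}")
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0:
        return {"statistic": -math.inf, "p_value": 0.0, "runs": runs, "passed": False}
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    z = (runs - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return {"statistic": float(z), "p_value": float(p), "runs": runs, "passed": bool(p >= alpha)}


def fit_michaelis_menten(S, V, errors=None) -> MMFit:
    """Weighted least-squares fit of ``V = Vmax * S / (Km + S)``.

    Requires >= 4 distinct substrate concentrations.  A concentration
    span below 5-fold, or a Km estimate collapsing toward zero / carrying
    an error larger than itself, marks the fit not ``identifiable``.
    """
    S = np.asarray(S, dtype=float)
    V = np.asarray(V, dtype=float)
    if S.shape != V.shape or S.ndim != 1:
        raise ValueError("S and V must be 1-D arrays of equal length")
    if len(np.unique(S)) < 4:
        raise ValueError("need >= 4 distinct substrate concentrations")
    if np.any(S <= 0):
        raise ValueError("substrate concentrations must be positive")

    flags: list[str] = []
    if S.max() / S.min() < 5.0:
        flags.append("concentration_range_below_5fold")

    def mm(s, vmax, km):
        return vmax * s / (km + s)

    half = np.interp(0.5 * V.max(), np.sort(V), S[np.argsort(V)])
    p0 = (float(V.max() * 1.2), float(max(half, S.min())))
    sigma = np.asarray(errors, float) if errors is not None else None
    try:
        popt, pcov = optimize.curve_fit(
            mm, S, V, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20_000,
            ftol=1e-14, xtol=1e-14,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = (float(v) for v in popt)
    perr = np.sqrt(np.abs(np.diag(pcov)))
    if km < S.min() / 100 or not np.isfinite(perr[1]) or perr[1] >= km:
        flags.append("Km_poorly_identified")
    identifiable = not flags
    return MMFit(
        Vmax=vmax,
        Km=km,
        Vmax_err=float(perr[0]),
        Km_err=float(perr[1]),
        residuals=V - mm(S, vmax, km),
        identifiable=identifiable,
        flags=flags,
    )
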