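"""Equilibrium stability: chemical denaturation, ligand linkage, thermal melts.

The two-state denaturation model with linear baselines is

    F(D) = [F_U0 + a*D + (F_N0 + b*D) * K] / (1 + K),
    K = exp(-(delta_g0 + m*D) / (R*T)),

with ``delta_g0`` the folding free energy at zero denaturant (positive =
unfolded favored, see :mod:`cagefold.kinetics`) and ``m > 0`` its
denaturant dependence.  The exponential weights the *native* term: for a
stable protein (``delta_g0 < 0``) the signal sits on the native baseline
at low denaturant and crosses to the unfolded baseline at the midpoint
``D_half = -delta_g0 / m``.

Free energies measured at several ligand concentrations extrapolate to
zero ligand through the linkage relation
``delta_g(S) = delta_g0 - R*T*ln(1 + S/Km)``.

Thermal melts yield only an *apparent* Tm — the extremum of the smoothed
first derivative dF/dT — because dye melts are not equilibrium unfolding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal as sp_signal
from scipy.special import expit

from .exceptions import FitConvergenceError
from .kinetics import DEFAULT_TEMPERATURE_K, PhysicalConstants, StabilityResult

__all__ = [
    "DenaturationCurve",
    "DenaturationFit",
    "MeltCurve",
    "TmResult",
    "two_state_denaturation_model",
    "fit_denaturation",
    "extrapolate_ligand_series",
    "melting_temperature",
]

_MIN_DENAT_POINTS = 10
_BASELINE_FRACTION_RESOLVED = 0.95


@dataclass
class DenaturationCurve:
    """Fluorescence vs denaturant at one fixed ligand concentration."""

    D: np.ndarray
    F: np.ndarray
    ligand_conc: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.D.ndim != 1 or self.D.shape != self.F.shape:
            raise ValueError("D and F must be 1-D arrays of equal length")
        if len(self.D) < _MIN_DENAT_POINTS:
            raise ValueError(f"denaturation curve needs >= {_MIN_DENAT_POINTS} points")
        if np.any(self.D < 0) or not np.all(np.diff(self.D) > 0):
            raise ValueError("denaturant concentrations must be non-negative and increasing")
        if not (np.all(np.isfinite(self.D)) and np.all(np.isfinite(self.F))):
            raise ValueError("D and F must be finite")

    def __len__(self) -> int:
        return len(self.D)


@dataclass
class DenaturationFit:
    """Six-parameter two-state fit of one denaturation curve."""

    delta_g0: float
    m: float
    F_N0: float
    b: float
    F_U0: float
    a: float
    errors: dict
    reduced_chi2: float
    residuals: np.ndarray
    ligand_conc: float
    temperature: float
    flags: list = field(default_factory=list)

    @property
    def midpoint(self) -> float:
        """Denaturant midpoint D_half = -delta_g0 / m (molar)."""
        return -self.delta_g0 / self.m


@dataclass
class MeltCurve:
    """Dye-fluorescence thermal melt on a roughly uniform temperature grid."""

    T_grid: np.ndarray  # celsius
    F: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.T_grid.ndim != 1 or self.T_grid.shape != self.F.shape:
            raise ValueError("T_grid and F must be 1-D arrays of equal length")
        steps = np.diff(self.T_grid)
        if len(steps) < 8 or np.any(steps <= 0):
            raise ValueError("T_grid must be increasing with >= 9 points")
        med = np.median(steps)
        if np.any(np.abs(steps - med) > 0.25 * med):
            raise ValueError("temperature increments must be roughly uniform")


@dataclass
class TmResult:
    """Apparent melting temperature from the dF/dT extremum."""

    tm: float
    derivative_peak_height: float
    smooth_window: int
    ambiguous: bool = False
    all_peaks: list = field(default_factory=list)


def two_state_denaturation_model(
    D, delta_g0: float, m: float, F_N0: float, b: float, F_U0: float, a: float,
    consts: PhysicalConstants = PhysicalConstants(),
):
    """Evaluate the two-state linear-baseline denaturation model (AU)."""
    D_arr = np.asarray(D, dtype=float)
    for name, val in (("delta_g0", delta_g0), ("m", m), ("F_N0", F_N0),
                      ("b", b), ("F_U0", F_U0), ("a", a)):
        if not math.isfinite(val):
            raise ValueError(f"parameter {name} must be finite")
    # native fraction via the logistic for overflow-free evaluation
    f_native = expit(-(delta_g0 + m * D_arr) / consts.RT)
    out = (F_U0 + a * D_arr) * (1.0 - f_native) + (F_N0 + b * D_arr) * f_native
    return out if D_arr.ndim else float(out)


def _denaturation_guess(curve: DenaturationCurve, consts: PhysicalConstants):
    D, F = curve.D, curve.F
    nb = max(3, len(D) // 5)
    b0, fn0 = np.polyfit(D[:nb], F[:nb], 1)
    a0, fu0 = np.polyfit(D[-nb:], F[-nb:], 1)
    native_line = fn0 + b0 * D
    unfolded_line = fu0 + a0 * D
    denom = unfolded_line - native_line
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    frac_u = np.clip((F - native_line) / denom, 0.0, 1.0)
    d_half = float(np.interp(0.5, frac_u, D))
    d25 = float(np.interp(0.25, frac_u, D))
    d75 = float(np.interp(0.75, frac_u, D))
    width = max(d75 - d25, 1e-3)
    m0 = max(2.0 * math.log(3.0) * consts.RT / width, 0.5)
    return (-m0 * d_half, m0, float(fn0), float(b0), float(fu0), float(a0))


def fit_denaturation(
    curve: DenaturationCurve,
    consts: PhysicalConstants = PhysicalConstants(),
    sigma=None,
) -> DenaturationFit:
    """Least-squares fit of the six two-state parameters.

    Flags curves whose native or unfolded baseline is not resolved
    (population < 95% at the corresponding end of the scan); ``delta_g0``
    from such fits is unreliable.
    """
    p0 = _denaturation_guess(curve, consts)

    def model(D, dg0, m, fn0, b, fu0, a):
        return two_state_denaturation_model(D, dg0, m, fn0, b, fu0, a, consts)

    sigma_arr = None
    if sigma is not None:
        sigma_arr = np.broadcast_to(np.asarray(sigma, float), curve.F.shape)

    # multi-start over the transition-slope guess: poorly resolved curves
    # have a shallow ridge in (delta_g0, m) and a single start can stall
    best = None
    last_error = None
    for m_factor in (1.0, 0.5, 2.0):
        start = (p0[0] * m_factor, p0[1] * m_factor) + p0[2:]
        try:
            popt, pcov = optimize.curve_fit(
                model, curve.D, curve.F, p0=start, sigma=sigma_arr,
                absolute_sigma=sigma_arr is not None,
                bounds=([-np.inf, 0.0] + [-np.inf] * 4, [np.inf] * 6),
                ftol=1e-14, xtol=1e-14, maxfev=50_000,
            )
        except RuntimeError as exc:
            last_error = exc
            continue
        ssr = float(np.sum((curve.F - model(curve.D, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise FitConvergenceError(
            f"denaturation fit did not converge (p0={p0}): {last_error}"
        ) from last_error
    _, popt, pcov = best

    dg0, m, fn0, b, fu0, a = (float(v) for v in popt)
    perr = np.sqrt(np.abs(np.diag(pcov)))
    names = ("delta_g0", "m", "F_N0", "b", "F_U0", "a")
    errors = {k: float(e) for k, e in zip(names, perr)}

    flags: list[str] = []
    frac_u_end = float(expit((dg0 + m * curve.D[-1]) / consts.RT))
    frac_n_start = float(expit(-(dg0 + m * curve.D[0]) / consts.RT))
    if frac_u_end < _BASELINE_FRACTION_RESOLVED:
        flags.append("unfolded_baseline_unresolved")
    if frac_n_start < _BASELINE_FRACTION_RESOLVED:
        flags.append("native_baseline_unresolved")
    dg_err = errors["delta_g0"]
    if not math.isfinite(dg_err) or dg_err > 1.0:
        flags.append("delta_g0_unreliable")

    residuals = curve.F - model(curve.D, *popt)
    dof = max(len(curve) - 6, 1)
    if sigma_arr is not None:
        red_chi2 = float(np.sum((residuals / sigma_arr) ** 2) / dof)
    else:
        red_chi2 = float(np.sum(residuals**2) / dof)
    return DenaturationFit(
        delta_g0=dg0, m=m, F_N0=fn0, b=b, F_U0=fu0, a=a,
        errors=errors, reduced_chi2=red_chi2, residuals=residuals,
        ligand_conc=curve.ligand_conc, temperature=curve.temperature, flags=flags,
    )


def extrapolate_ligand_series(
    fits,
    Km: float = 13e-6,
    consts: PhysicalConstants = PhysicalConstants(),
) -> StabilityResult:
    """Zero-ligand folding free energy via the linkage relation.

    ``fits`` is a list of :class:`DenaturationFit` or tuples
    ``(ligand_conc, delta_g0[, err])``.  Each measurement is shifted by
    ``+R*T*ln(1 + S/Km)`` and the shifted values are combined by a
    weighted mean — the least-squares solution for the single free
    parameter delta_g0.
    """
    if Km <= 0:
        raise ValueError("Km must be positive")
    if len(fits) == 0:
        raise ValueError("need at least one measurement")
    concs, dgs, errs, temps = [], [], [], []
    for item in fits:
        if isinstance(item, DenaturationFit):
            concs.append(item.ligand_conc)
            dgs.append(item.delta_g0)
            errs.append(item.errors.get("delta_g0"))
            temps.append(item.temperature)
        else:
            concs.append(item[0])
            dgs.append(item[1])
            errs.append(item[2] if len(item) > 2 else None)
            temps.append(consts.T)
    if max(temps) - min(temps) > 0.5:
        raise ValueError("inconsistent temperatures across denaturation fits")

    shifted = np.array(dgs) + consts.RT * np.log1p(np.asarray(concs, float) / Km)
    have_errs = all(e is not None and e > 0 for e in errs)
    if have_errs:
        w = 1.0 / np.asarray(errs, float) ** 2
        dg0 = float(np.sum(w * shifted) / np.sum(w))
        se = float(1.0 / math.sqrt(np.sum(w)))
    else:
        dg0 = float(np.mean(shifted))
        se = float(np.std(shifted, ddof=1) / math.sqrt(len(shifted))) if len(shifted) > 1 else None
    return StabilityResult(dg0, consts.T, "extrapolation", se)


def melting_temperature(curve: MeltCurve, smooth_window: int = 11) -> TmResult:
    """Apparent Tm from the extremum of the smoothed first derivative.

    F(T) is smoothed with a local-quadratic (Savitzky-Golay) filter whose
    derivative gives dF/dT; the returned Tm is the parabolically refined
    location of the largest-|dF/dT| interior extremum.  An extremum on
    the scan boundary means no transition was captured and raises.
    Secondary peaks within 80% of the main one are reported and flagged.
    """
    if smooth_window % 2 == 0 or smooth_window < 5:
        raise ValueError("smooth_window must be odd and >= 5")
    T, F = curve.T_grid, curve.F
    if smooth_window >= len(T):
        raise ValueError("smooth_window larger than the melt curve")
    step = float(np.median(np.diff(T)))
    dF = sp_signal.savgol_filter(F, smooth_window, polyorder=2, deriv=1, delta=step)
    margin = smooth_window // 2
    interior = slice(margin, len(T) - margin)
    mag = np.abs(dF[interior])
    k = int(np.argmax(mag)) + margin
    if k <= margin or k >= len(T) - margin - 1:
        raise ValueError("derivative extremum on the scan boundary: no transition captured")
    if mag.max() < 2.0 * np.median(mag):
        raise ValueError("no transition captured: derivative peak not prominent")

    # parabolic refinement of the peak position on |dF/dT|
    ym, y0, yp = np.abs(dF[k - 1]), np.abs(dF[k]), np.abs(dF[k + 1])
    denom = ym - 2.0 * y0 + yp
    shift = 0.0 if denom >= 0 else 0.5 * (ym - yp) / denom
    tm = float(T[k] + shift * step)

    peaks, props = sp_signal.find_peaks(np.abs(dF), height=0.8 * y0)
    peak_temps = [float(T[p]) for p in peaks if margin <= p < len(T) - margin]
    ambiguous = len(peak_temps) > 1
    return TmResult(
        tm=tm,
        derivative_peak_height=float(dF[k]),
        smooth_window=smooth_window,
        ambiguous=ambiguous,
        all_peaks=peak_temps if ambiguous else [tm],
    )
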