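"""Rate-constant inference from the substrate dependence of the lag rate.

Fits ``lambda(S) = k1 + k_minus1 / (Ka*S + 1)``, maps the reduced
chi-square surface over (k1, k_minus1) with Ka profiled out at every
node, derives profile confidence intervals, and classifies the kinetic
mechanism from the sign of the lambda-vs-S trend (decreasing =
conformational selection; increasing = induced fit or substrate
penetration, which the data cannot distinguish).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import FitConvergenceError
from .kinetics import DEFAULT_TEMPERATURE_K, SchemeRates

__all__ = [
    "LambdaSeries",
    "LambdaFit",
    "GridSpec",
    "Chi2Surface",
    "fit_lambda_curve",
    "chi2_surface",
    "classify_mechanism",
]

_N_PARAMS = 3  # k1, k_minus1, Ka


@dataclass
class LambdaSeries:
    """Observed lag rate constants at several substrate concentrations."""

    S: np.ndarray
    lam: np.ndarray
    lam_err: np.ndarray | None = None
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.S.ndim != 1 or self.S.shape != self.lam.shape:
            raise ValueError("S and lam must be 1-D arrays of equal length")
        if len(np.unique(self.S)) != len(self.S):
            raise ValueError("substrate concentrations must be distinct (average duplicates first)")
        if np.any(self.S < 0):
            raise ValueError("substrate concentrations must be non-negative")
        if np.any(self.lam <= 0):
            raise ValueError("lambda values must be positive")
        if self.lam_err is not None:
            self.lam_err = np.asarray(self.lam_err, dtype=float)
            if self.lam_err.shape != self.lam.shape or np.any(self.lam_err <= 0):
                raise ValueError("lam_err must match lam and be positive")

    @classmethod
    def from_measurements(cls, S, lam, temperature: float = DEFAULT_TEMPERATURE_K) -> "LambdaSeries":
        """Build a series from raw (possibly replicated) measurements.

        Replicates at the same concentration are averaged; the pooled
        within-group standard deviation supplies a common standard error
        of the mean for every point (replicate counts are typically 2,
        so per-group scatter alone would be unreliable).
        """
        S = np.asarray(S, float)
        lam = np.asarray(lam, float)
        uniq = np.unique(S)
        means = np.array([lam[S == s].mean() for s in uniq])
        counts = np.array([np.sum(S == s) for s in uniq])
        ss = sum(float(np.sum((lam[S == s] - m) ** 2)) for s, m in zip(uniq, means))
        dof = int(np.sum(counts - 1))
        errs = None
        if dof > 0 and ss > 0:
            pooled_sd = math.sqrt(ss / dof)
            errs = pooled_sd / np.sqrt(counts)
        return cls(S=uniq, lam=means, lam_err=errs, temperature=temperature)

    def weights(self) -> np.ndarray:
        if self.lam_err is None:
            return np.ones_like(self.lam)
        return 1.0 / self.lam_err**2

    def __len__(self) -> int:
        return len(self.S)


@dataclass
class LambdaFit:
    """Result of fitting lambda(S); rates carry k1, k_minus1 and Ka."""

    rates: SchemeRates
    k1_err: float
    k_minus1_err: float
    Ka_err: float
    reduced_chi2: float
    confidence_intervals: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    residuals: np.ndarray | None = None


@dataclass(frozen=True)
class GridSpec:
    """Chi-square surface grid: log-spaced nodes spanning +/- span_sigma
    standard errors around each estimate (explicit ranges override)."""

    n_k1: int = 101
    n_k_minus1: int = 101
    n_Ka: int = 481
    span_sigma: float = 3.0
    k1_range: tuple | None = None
    k_minus1_range: tuple | None = None


@dataclass
class Chi2Surface:
    """Reduced chi-square over (k1, k_minus1) with Ka profiled out."""

    k1_axis: np.ndarray
    k_minus1_axis: np.ndarray
    values: np.ndarray  # shape (len(k1_axis), len(k_minus1_axis)), reduced chi2
    dof: int
    fit: LambdaFit

    def marginal_interval(self, param: str, delta_chi2: float = 1.0) -> tuple[float, float]:
        """Interval where the per-axis profile satisfies chi2 <= min + delta_chi2.

        ``param`` is ``"k1"`` or ``"k_minus1"``.  Crossings are located by
        linear interpolation of the profile in log-parameter coordinates.
        """
        if param == "k1":
            axis, profile = self.k1_axis, self.values.min(axis=1) * self.dof
        elif param == "k_minus1":
            axis, profile = self.k_minus1_axis, self.values.min(axis=0) * self.dof
        else:
            raise ValueError(f"param must be 'k1' or 'k_minus1', got {param!r}")
        threshold = profile.min() + delta_chi2
        inside = profile <= threshold
        idx = np.nonzero(inside)[0]
        log_axis = np.log(axis)
        lo_i, hi_i = int(idx[0]), int(idx[-1])
        lo = axis[lo_i]
        hi = axis[hi_i]
        if lo_i > 0:
            f = (threshold - profile[lo_i - 1]) / (profile[lo_i] - profile[lo_i - 1])
            lo = math.exp(log_axis[lo_i - 1] + f * (log_axis[lo_i] - log_axis[lo_i - 1]))
        if hi_i < len(axis) - 1:
            f = (threshold - profile[hi_i + 1]) / (profile[hi_i] - profile[hi_i + 1])
            hi = math.exp(log_axis[hi_i + 1] + f * (log_axis[hi_i] - log_axis[hi_i + 1]))
        return float(lo), float(hi)

    def to_arrays(self) -> dict:
        """Flat dict of columns (k1, k_minus1, reduced_chi2) for export."""
        K1, K2 = np.meshgrid(self.k1_axis, self.k_minus1_axis, indexing="ij")
        return {
            "k1_per_s": K1.ravel(),
            "k_minus1_per_s": K2.ravel(),
            "reduced_chi2": self.values.ravel(),
        }


def _lambda_model(S, k1, k_minus1, Ka):
    return k1 + k_minus1 / (Ka * S + 1.0)


def _initial_guess(series: LambdaSeries) -> tuple[float, float, float]:
    lam = series.lam
    k1_0 = max(float(lam.min()) * 0.9, 1e-12)
    km1_0 = max(float(lam.max() - lam.min()), 0.1 * float(lam.mean()))
    # half-decay concentration -> Ka ~ 1/S_half
    target = k1_0 + km1_0 / 2.0
    order = np.argsort(series.S)
    s_sorted, lam_sorted = series.S[order], lam[order]
    below = np.nonzero(lam_sorted <= target)[0]
    positive = s_sorted[s_sorted > 0]
    s_half = float(s_sorted[below[0]]) if len(below) and s_sorted[below[0]] > 0 else (
        float(np.median(positive)) if len(positive) else 1.0
    )
    return k1_0, km1_0, 1.0 / s_half


def fit_lambda_curve(series: LambdaSeries, fix_Ka: float | None = None) -> LambdaFit:
    """Weighted least-squares fit of lambda(S) to the fast-binding form.

    Parameters are constrained non-negative; errors come from the
    covariance at the optimum (absolute when lambda errors are supplied).
    A flat series leaves k_minus1 and Ka unidentifiable, which is flagged
    rather than raised.  Profile confidence intervals (delta chi2 = 1)
    are attached for k1 and k_minus1.
    """
    if len(series) < 4:
        raise ValueError("need >= 4 distinct substrate concentrations")
    sigma = series.lam_err if series.lam_err is not None else np.ones_like(series.lam)
    k1_0, km1_0, ka_0 = _initial_guess(series)

    if fix_Ka is not None and fix_Ka <= 0:
        raise ValueError("fix_Ka must be positive")
    # fit in log-parameter space: enforces positivity and conditions the
    # problem (the raw parameters span seven orders of magnitude)
    p0 = (k1_0, km1_0) if fix_Ka is not None else (k1_0, km1_0, ka_0)

    def resid(q):
        p = np.exp(q)
        ka = fix_Ka if fix_Ka is not None else p[2]
        return (series.lam - _lambda_model(series.S, p[0], p[1], ka)) / sigma

    sol = optimize.least_squares(
        resid, np.log(p0), method="lm", ftol=1e-15, xtol=1e-15, gtol=1e-15,
        max_nfev=50_000,
    )
    if not sol.success:
        raise FitConvergenceError(f"lambda(S) fit did not converge (p0={p0}): {sol.message}")
    p_hat = np.exp(sol.x)
    n_free = len(p_hat)
    # covariance back in natural units: dp = p * dq
    jtj = sol.jac.T @ sol.jac
    cov_q = np.linalg.pinv(jtj)
    if series.lam_err is None:
        dof_fit = max(len(series) - n_free, 1)
        cov_q = cov_q * (2.0 * sol.cost / dof_fit)
    cov = cov_q * np.outer(p_hat, p_hat)
    perr = np.sqrt(np.abs(np.diag(cov)))

    if fix_Ka is not None:
        k1, km1, ka = float(p_hat[0]), float(p_hat[1]), float(fix_Ka)
        k1_err, km1_err, ka_err = float(perr[0]), float(perr[1]), 0.0
    else:
        k1, km1, ka = (float(v) for v in p_hat)
        k1_err, km1_err, ka_err = (float(v) for v in perr)

    flags: list[str] = []
    lam_span = float(series.lam.max() - series.lam.min())
    if lam_span < 1e-3 * float(series.lam.mean()) or (
        math.isfinite(km1_err) and km1 > 0 and km1_err >= km1
    ) or km1 <= 1e-12 * series.lam.mean():
        flags += ["k_minus1_unidentifiable", "Ka_unidentifiable"]

    w = series.weights()
    residuals = series.lam - _lambda_model(series.S, k1, km1, ka)
    dof = max(len(series) - n_free, 1)
    red_chi2 = float(np.sum(w * residuals**2) / dof)

    rates = SchemeRates(k1=k1, k_minus1=km1, Ka=ka, k1_err=k1_err, k_minus1_err=km1_err)
    fit = LambdaFit(
        rates=rates,
        k1_err=k1_err,
        k_minus1_err=km1_err,
        Ka_err=ka_err,
        reduced_chi2=red_chi2,
        flags=flags,
        residuals=residuals,
    )
    if not flags:
        try:
            surface = chi2_surface(series, fit)
            fit.confidence_intervals = {
                "k1": surface.marginal_interval("k1"),
                "k_minus1": surface.marginal_interval("k_minus1"),
            }
        except (ValueError, FloatingPointError):  # degenerate error estimates
            fit.flags.append("confidence_intervals_unavailable")
    return fit


def _axis_from_profile(profile, estimate: float, anchor: float, n: int,
                       threshold: float, explicit: tuple | None) -> np.ndarray:
    """Log-spaced axis covering the region where ``profile(x) <= threshold``.

    Bounds are found by multiplicative expansion from ``anchor`` (the
    estimate, or a data-driven scale when the estimate collapsed to the
    zero boundary), so the grid always spans the confidence region even
    for weakly identified parameters.
    """
    if explicit is not None:
        lo, hi = explicit
        if not (0 < lo < hi):
            raise ValueError("explicit grid range must satisfy 0 < lo < hi")
    else:
        hi = anchor
        for _ in range(400):
            if profile(hi) > threshold:
                break
            hi *= 1.5
        lo = anchor
        for _ in range(400):
            if profile(lo) > threshold or lo < anchor * 1e-10:
                break
            lo /= 1.5
    axis = np.geomspace(lo, hi, n)
    if lo <= estimate <= hi:
        axis = np.unique(np.concatenate([axis, [estimate]]))
    return axis


def chi2_surface(series: LambdaSeries, fit: LambdaFit, grid_spec: GridSpec = GridSpec()) -> Chi2Surface:
    """Reduced chi-square surface over (k1, k_minus1), Ka re-optimized per node.

    The profile over Ka is computed on a dense log grid spanning three
    decades around the fitted value, refined by a parabolic vertex step
    in log-Ka; the whole surface is evaluated vectorized.  Axes are
    log-spaced and sized so the profile chi-square rises by at least
    ``span_sigma**2`` at the edges (>= span_sigma standard errors each
    way); the fitted (k1, k_minus1) are inserted so the surface minimum
    reproduces ``fit.reduced_chi2``.  Raises if explicit grid ranges do
    not contain the fitted minimum.
    """
    k1_hat, km1_hat, ka_hat = fit.rates.k1, fit.rates.k_minus1, fit.rates.Ka
    for rng, est, name in (
        (grid_spec.k1_range, k1_hat, "k1"),
        (grid_spec.k_minus1_range, km1_hat, "k_minus1"),
    ):
        if rng is not None and not (rng[0] <= est <= rng[1]):
            raise ValueError(f"grid for {name} does not contain the fitted minimum")

    ka_grid = ka_hat * np.geomspace(1e-3, 1e3, grid_spec.n_Ka | 1)  # odd count hits ka_hat

    S, lam = series.S, series.lam
    w = series.weights()
    # chi2(k1, km1, Ka) expands into sums over the data that depend on Ka
    # only through u_i = 1/(Ka*S_i + 1); everything broadcasts.
    u = 1.0 / (ka_grid[:, None] * S[None, :] + 1.0)  # (nKa, ndata)
    Sw = float(np.sum(w))
    Swl = float(np.sum(w * lam))
    Swll = float(np.sum(w * lam * lam))
    Swu = u @ w                 # (nKa,)
    Swuu = (u * u) @ w
    Swlu = u @ (w * lam)

    def chi2_at(k1, km1):
        return (
            Swll - 2.0 * k1 * Swl + k1**2 * Sw
            + km1**2 * Swuu - 2.0 * km1 * Swlu + 2.0 * k1 * km1 * Swu
        )

    def profile_k1(x):
        # km1 optimized in closed form per Ka node, then min over Ka
        km1_opt = np.maximum((Swlu - x * Swu) / Swuu, 0.0)
        return float(np.min(chi2_at(x, km1_opt)))

    def profile_km1(x):
        k1_opt = np.maximum((Swl - x * Swu) / Sw, 0.0)
        return float(np.min(chi2_at(k1_opt, x)))

    chi2_min_raw = fit.reduced_chi2 * max(len(series) - _N_PARAMS, 1)
    threshold = chi2_min_raw + max(grid_spec.span_sigma**2, 1.0)
    lam_scale = float(lam.min())
    k1_axis = _axis_from_profile(
        profile_k1, k1_hat, max(k1_hat, 1e-3 * lam_scale),
        grid_spec.n_k1, threshold, grid_spec.k1_range,
    )
    km1_axis = _axis_from_profile(
        profile_km1, km1_hat, max(km1_hat, 1e-3 * lam_scale),
        grid_spec.n_k_minus1, threshold, grid_spec.k_minus1_range,
    )

    k1g = k1_axis[:, None, None]
    km1g = km1_axis[None, :, None]
    chi2 = (
        Swll
        - 2.0 * k1g * Swl
        + k1g**2 * Sw
        + km1g**2 * Swuu[None, None, :]
        - 2.0 * km1g * Swlu[None, None, :]
        + 2.0 * k1g * km1g * Swu[None, None, :]
    )
    idx = np.argmin(chi2, axis=2)
    n_ka = chi2.shape[2]
    i0 = np.clip(idx, 1, n_ka - 2)
    take = np.take_along_axis
    ym = take(chi2, (i0 - 1)[..., None], axis=2)[..., 0]
    y0 = take(chi2, i0[..., None], axis=2)[..., 0]
    yp = take(chi2, (i0 + 1)[..., None], axis=2)[..., 0]
    # parabolic vertex in log-Ka (uniform log spacing); guard flat curvature
    denom = ym - 2.0 * y0 + yp
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = y0 - 0.125 * (yp - ym) ** 2 / denom
    profiled = np.where((denom > 0) & (idx == i0), vertex, y0)
    profiled = np.minimum(profiled, np.min(chi2, axis=2))

    dof = max(len(series) - _N_PARAMS, 1)
    surface = Chi2Surface(
        k1_axis=k1_axis,
        k_minus1_axis=km1_axis,
        values=profiled / dof,
        dof=dof,
        fit=fit,
    )
    return surface


def classify_mechanism(series: LambdaSeries, alpha: float = 0.05) -> str:
    """Mechanism call from the lambda-vs-S trend.

    A significantly decreasing trend (two-sided p < ``alpha`` on the
    weighted linear slope) returns ``"conformational_selection"``; a
    significantly increasing one ``"induced_fit_or_penetration"`` —
    induced fit and substrate penetration into the cage predict the same
    sign and cannot be separated here.  Otherwise ``"indeterminate"``.
    """
    if len(series) < 4:
        raise ValueError("need >= 4 points to classify a trend")
    S, lam = series.S, series.lam
    if series.lam_err is not None:
        # known per-point sigma: weighted LS slope with a normal z-test
        w = series.weights()
        X = np.column_stack([np.ones_like(S), S])
        XtW = X.T * w
        cov = np.linalg.inv(XtW @ X)
        beta = cov @ (XtW @ lam)
        slope = float(beta[1])
        se = math.sqrt(cov[1, 1])
        p = 2.0 * stats.norm.sf(abs(slope / se))
    else:
        res = stats.linregress(S, lam)
        slope, p = float(res.slope), float(res.pvalue)
    if p < alpha:
        return "conformational_selection" if slope < 0 else "induced_fit_or_penetration"
    return "indeterminate"
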