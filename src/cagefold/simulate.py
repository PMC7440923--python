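"""Synthetic-data generators with recorded ground truth.

Every pipeline stage has a generator here whose output it can consume
unmodified; every generator returns ``(data, truth)`` where ``truth`` is
a plain dict naming the parameters, the noise model and the seed.  All
randomness flows through one seeded ``numpy`` generator per call, so a
fixed seed reproduces the data bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .anisotropy import AnisotropyDecay
from .equilibrium import DenaturationCurve, MeltCurve, two_state_denaturation_model
from .kinetics import PhysicalConstants, SchemeRates, delta_g_ligand_shift, lambda_of_substrate
from .progress import DEFAULT_EXTINCTION_PATH, ProgressCurve
from .rates import LambdaSeries

__all__ = [
    "NoiseSpec",
    "OpticsConfig",
    "SchemeTrajectory",
    "simulate_scheme_ode",
    "simulate_lambda_series",
    "simulate_denaturation_curve",
    "simulate_melt_curve",
    "simulate_anisotropy",
]

R0_MIN, R0_MAX = -0.2, 0.4


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: Gaussian (absolute or relative scale) or Poisson.

    ``relative=True`` interprets ``scale`` as a fraction of each clean
    value (Gaussian only).  The seed is recorded in every truth manifest.
    """

    kind: str = "gaussian"
    scale: float = 0.0
    seed: int = 0
    relative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, clean: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or self.rng()
        if self.kind == "none" or (self.kind == "gaussian" and self.scale == 0):
            return np.array(clean, dtype=float, copy=True)
        if self.kind == "gaussian":
            sd = self.scale * np.abs(clean) if self.relative else self.scale
            return clean + rng.normal(0.0, 1.0, np.shape(clean)) * sd
        return rng.poisson(np.maximum(clean, 0.0)).astype(float)


@dataclass(frozen=True)
class OpticsConfig:
    """Conversion from cofactor concentration to A340 signal.

    ``epsilon_path`` is the absorbance change per molar of NADPH
    consumed (delta-epsilon 6220 M^-1 cm^-1 times an effective 0.5 cm
    plate pathlength by default).
    """

    epsilon_path: float = DEFAULT_EXTINCTION_PATH


@dataclass
class SchemeTrajectory:
    """Hidden state of the folding-binding-catalysis simulation."""

    t: np.ndarray
    E_U: np.ndarray
    E_F: np.ndarray
    ES: np.ndarray
    S: np.ndarray
    N: np.ndarray
    P: np.ndarray
    rates: SchemeRates

    def conservation_error(self) -> tuple[float, float]:
        """Max relative drift of enzyme and substrate conservation."""
        E_tot = self.E_U + self.E_F + self.ES
        e_err = float(np.max(np.abs(E_tot - E_tot[0])) / E_tot[0])
        S_tot = self.S + self.ES + self.P
        s_err = float(np.max(np.abs(S_tot - S_tot[0])) / S_tot[0])
        return e_err, s_err


def simulate_scheme_ode(
    rates: SchemeRates,
    E0: float,
    S0: float,
    N0: float,
    t_grid,
    optics: OpticsConfig = OpticsConfig(),
    noise: NoiseSpec | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
    initial_folded_fraction: float | None = 0.0,
) -> tuple[ProgressCurve, SchemeTrajectory]:
    """Integrate the folding-binding-catalysis scheme and emit an A340 trace.

    By default the enzyme starts fully unfolded — the initial condition
    under which the product curve shows the full lag the closed-form lag
    model describes (activity building from zero).  Pass
    ``initial_folded_fraction=None`` to start instead from the
    pre-substrate folding equilibrium (E_U : E_F = k_minus1 : k1), or an
    explicit folded fraction in [0, 1].  Catalysis consumes one bound
    substrate and one cofactor per turnover, regenerating the folded
    enzyme; the observable is ``epsilon_path * N(t)``, the falling
    cofactor absorbance.  Requires explicit ``k2`` and ``k_minus2``.

    Returns the observable :class:`ProgressCurve` plus the hidden
    :class:`SchemeTrajectory` ground truth.
    """
    if rates.k2 is None or rates.k_minus2 is None:
        raise ValueError("simulation requires explicit k2 and k_minus2")
    for name, val in (("E0", E0), ("S0", S0), ("N0", N0)):
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)
    k1, km1 = rates.k1, rates.k_minus1
    k2, km2, kcat = rates.k2, rates.k_minus2, rates.kcat

    if initial_folded_fraction is None:
        ktot = k1 + km1
        ef0 = E0 * (k1 / ktot) if ktot > 0 else 0.0
    else:
        if not (0.0 <= initial_folded_fraction <= 1.0):
            raise ValueError("initial_folded_fraction must lie in [0, 1]")
        ef0 = E0 * initial_folded_fraction
    y0 = [E0 - ef0, ef0, 0.0, S0, N0, 0.0]

    def rhs(_t, y):
        e_u, e_f, es, s, n, _p = y
        bind = k2 * e_f * s
        unbind = km2 * es
        turn = kcat * es
        return [
            -k1 * e_u + km1 * e_f,
            k1 * e_u - km1 * e_f - bind + unbind + turn,
            bind - unbind - turn,
            -bind + unbind,
            -turn,
            turn,
        ]

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
        method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed (method={method}, rtol={rtol}, atol={atol}): {sol.message}"
        )
    e_u, e_f, es, s, n, p = sol.y
    signal = optics.epsilon_path * n
    if noise is not None:
        signal = noise.apply(signal)
    curve = ProgressCurve(
        times=t_grid, signal=signal,
        substrate_conc=S0, cofactor_conc=N0, enzyme_conc=E0,
        label="simulated",
    )
    traj = SchemeTrajectory(t=t_grid, E_U=e_u, E_F=e_f, ES=es, S=s, N=n, P=p, rates=rates)
    return curve, traj


def simulate_lambda_series(
    rates: SchemeRates,
    S_list,
    noise: NoiseSpec | None = None,
) -> tuple[LambdaSeries, dict]:
    """Sample lambda(S) from the fast-binding closed form, plus noise.

    With Gaussian noise the known per-point sigma is attached as
    ``lam_err`` so downstream fits are correctly weighted.
    """
    S = np.asarray(S_list, dtype=float)
    clean = lambda_of_substrate(S, rates)
    truth = {
        "k1": rates.k1, "k_minus1": rates.k_minus1, "Ka": rates.Ka,
        "noise": asdict(noise) if noise else None,
    }
    if noise is None or noise.kind == "none" or noise.scale == 0:
        return LambdaSeries(S=S, lam=clean), truth
    if noise.kind != "gaussian":
        raise ValueError("lambda series supports gaussian noise only")
    sd = noise.scale * clean if noise.relative else np.full_like(clean, noise.scale)
    lam = clean + noise.rng().normal(0.0, 1.0, clean.shape) * sd
    lam = np.maximum(lam, 1e-12)
    return LambdaSeries(S=S, lam=lam, lam_err=sd), truth


def simulate_denaturation_curve(
    delta_g0: float,
    m: float,
    D_grid,
    F_N0: float = 100.0,
    b: float = -0.5,
    F_U0: float = 10.0,
    a: float = 0.5,
    ligand_conc: float = 0.0,
    Km: float = 13e-6,
    noise: NoiseSpec | None = None,
    consts: PhysicalConstants = PhysicalConstants(),
) -> tuple[DenaturationCurve, dict]:
    """Two-state denaturation curve at a fixed ligand concentration.

    ``delta_g0`` is the zero-ligand free energy; the curve is generated
    at the linkage-shifted value for ``ligand_conc``.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    D = np.asarray(D_grid, dtype=float)
    dg_at_ligand = delta_g_ligand_shift(delta_g0, ligand_conc, Km, consts)
    clean = two_state_denaturation_model(D, dg_at_ligand, m, F_N0, b, F_U0, a, consts)
    F = noise.apply(clean) if noise is not None else clean
    truth = {
        "delta_g0": delta_g0, "delta_g_at_ligand": dg_at_ligand, "m": m,
        "F_N0": F_N0, "b": b, "F_U0": F_U0, "a": a,
        "ligand_conc": ligand_conc, "Km": Km, "temperature": consts.T,
        "noise": asdict(noise) if noise else None,
    }
    curve = DenaturationCurve(D=D, F=F, ligand_conc=ligand_conc, temperature=consts.T)
    return curve, truth


def simulate_melt_curve(
    tm: float,
    width: float = 1.5,
    T_start: float = 4.0,
    T_stop: float = 94.0,
    T_step: float = 0.5,
    F_N0: float = 10.0,
    b: float = 0.02,
    F_U0: float = 110.0,
    a: float = -0.05,
    noise: NoiseSpec | None = None,
    label: str = "",
) -> tuple[MeltCurve, dict]:
    """Two-state apparent-equilibrium dye melt with linear baselines.

    The unfolded fraction is a logistic of width ``width`` (celsius)
    centered at ``tm``; no claim is made of matching dye photophysics.
    """
    if width <= 0:
        raise ValueError("transition width must be positive")
    if not (T_start < tm < T_stop):
        raise ValueError("tm must lie inside the scanned range")
    T = np.arange(T_start, T_stop + 0.5 * T_step, T_step)
    frac_u = expit((T - tm) / width)
    clean = (F_N0 + b * T) * (1.0 - frac_u) + (F_U0 + a * T) * frac_u
    F = noise.apply(clean) if noise is not None else clean
    truth = {
        "tm": tm, "width": width, "F_N0": F_N0, "b": b, "F_U0": F_U0, "a": a,
        "noise": asdict(noise) if noise else None,
    }
    return MeltCurve(T_grid=T, F=F, label=label), truth


def simulate_anisotropy(
    r0: float,
    theta: float,
    lifetime: float = 2.8,
    total_counts: float = 1e6,
    G: float = 1.0,
    window: float = 50.0,
    dt: float = 0.016,
    background: float = 0.0,
    noise: NoiseSpec | None = None,
) -> tuple[AnisotropyDecay, dict]:
    """Polarized photon-count decays for a single rotational component.

    The total intensity decays with the fluorescence ``lifetime`` (ns) and
    the anisotropy as ``r0 * exp(-t/theta)``; channel intensities follow
    I_par = I*(1+2r)/3 and I_perp = I*(1-r)/3, with the detected
    perpendicular channel scaled by 1/G.  Counts are normalized to
    ``total_counts`` over a ``window`` ns range binned at ``dt`` ns
    (default 16 ps), then Poisson-sampled when ``noise.kind ==
    "poisson"``; ``noise=None`` returns noiseless expected counts.
    """
    if not (R0_MIN <= r0 <= R0_MAX):
        raise ValueError(f"r0 must lie in [{R0_MIN}, {R0_MAX}]")
    if theta <= 0 or lifetime <= 0 or window <= 0 or dt <= 0:
        raise ValueError("theta, lifetime, window and dt must be positive")
    t = np.arange(0.0, window, dt)
    r = r0 * np.exp(-t / theta)
    intensity = np.exp(-t / lifetime)
    par = intensity * (1.0 + 2.0 * r) / 3.0
    perp = intensity * (1.0 - r) / 3.0 / G  # detected counts before G correction
    norm = total_counts / (par.sum() + perp.sum())
    par, perp = par * norm + background, perp * norm + background
    if noise is not None:
        if noise.kind != "poisson":
            raise ValueError("anisotropy decays use poisson noise")
        rng = noise.rng()
        par = rng.poisson(par).astype(float)
        perp = rng.poisson(perp).astype(float)
    truth = {
        "r0": r0, "theta": theta, "lifetime": lifetime,
        "total_counts": total_counts, "G": G, "window": window, "dt": dt,
        "background": background, "noise": asdict(noise) if noise else None,
    }
    decay = AnisotropyDecay(
        t=t, I_par=par, I_perp=perp, G=G,
        background_par=background, background_perp=background,
    )
    return decay, truth
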