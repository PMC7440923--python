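"""Closed-form kinetic and thermodynamic identities of the folding-binding scheme.

The reaction scheme is a three-state chain

    E_U  <=>  E_F  <=>  E_F·S

with folding/unfolding rate constants ``k1``/``k_minus1`` and substrate
association/dissociation constants ``k2``/``k_minus2`` (association
constant ``Ka = k2 / k_minus2``).  When ligand binding is fast relative to
folding, the observed lag-phase rate constant reduces to
``lambda = k1 + k_minus1 / (Ka*S + 1)``, which decreases with substrate
concentration — the kinetic signature of conformational selection.

Sign convention
---------------
``delta_g`` throughout this package is the *folding* free energy:
positive values mean the unfolded state is favored
(``delta_g = R*T*ln(k_minus1/k1)``), negative values mean the folded state
is stable.  Every report emitted by the pipeline restates this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "PhysicalConstants",
    "SchemeRates",
    "StabilityResult",
    "lag_progress_model",
    "lambda_of_substrate",
    "delta_g_from_rates",
    "delta_g_ligand_shift",
    "destabilization",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987e-3

#: Default assay temperature, 23 degC.
DEFAULT_TEMPERATURE_K = 296.15

_KA_RTOL = 1e-9


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant and absolute temperature used in free-energy formulas.

    Parameters
    ----------
    R : float
        Gas constant in kcal mol^-1 K^-1.
    T : float
        Absolute temperature in kelvin.
    """

    R: float = GAS_CONSTANT_KCAL
    T: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not (self.R > 0):
            raise ValueError(f"gas constant must be positive, got {self.R}")
        if not (self.T > 0):
            raise ValueError(f"absolute temperature must be positive, got {self.T}")

    @property
    def RT(self) -> float:
        """Thermal energy R*T in kcal mol^-1."""
        return self.R * self.T


@dataclass(frozen=True)
class SchemeRates:
    """Rate constants of the folding-binding-catalysis scheme.

    Parameters
    ----------
    k1 : float
        Folding rate constant, s^-1.
    k_minus1 : float
        Unfolding rate constant, s^-1.
    k2, k_minus2 : float, optional
        Substrate association (M^-1 s^-1) and dissociation (s^-1) rate
        constants.  If both are given, ``Ka`` is derived (or checked
        against an explicit value to relative tolerance 1e-9).
    Ka : float, optional
        Substrate association constant, M^-1.
    kcat : float
        Catalytic turnover, s^-1; used by the simulator only.
    k1_err, k_minus1_err : float, optional
        Standard errors for uncertainty propagation.
    """

    k1: float
    k_minus1: float
    k2: float | None = None
    k_minus2: float | None = None
    Ka: float | None = None
    kcat: float = 0.0
    k1_err: float | None = None
    k_minus1_err: float | None = None

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2", "k_minus2", "Ka", "kcat"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {value}")
        if self.k2 is not None and self.k_minus2 is not None:
            if self.k_minus2 <= 0:
                raise ValueError("k_minus2 must be positive to define Ka")
            derived = self.k2 / self.k_minus2
            if self.Ka is None:
                object.__setattr__(self, "Ka", derived)
            elif not math.isclose(self.Ka, derived, rel_tol=_KA_RTOL):
                raise ValueError(
                    f"inconsistent association constant: Ka={self.Ka} but k2/k_minus2={derived}"
                )

    def with_errors(self, k1_err: float, k_minus1_err: float) -> "SchemeRates":
        """Return a copy carrying standard errors on k1 and k_minus1."""
        return replace(self, k1_err=k1_err, k_minus1_err=k_minus1_err)


@dataclass(frozen=True)
class StabilityResult:
    """A folding free energy with provenance.

    ``delta_g`` follows the folding convention (positive = unfolded
    favored).  ``source`` is one of ``{"rates", "denaturation",
    "extrapolation"}``.
    """

    delta_g: float
    temperature: float
    source: str
    uncertainty: float | None = None

    _SOURCES = ("rates", "denaturation", "extrapolation")

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")
        if self.source not in self._SOURCES:
            raise ValueError(f"source must be one of {self._SOURCES}, got {self.source!r}")
        if self.uncertainty is not None and not (
            math.isfinite(self.uncertainty) and self.uncertainty >= 0
        ):
            raise ValueError("uncertainty must be finite and non-negative")


def lag_progress_model(t, V: float, A: float, lam: float):
    """Product signal with a lag phase: ``V*t + A*(exp(-lam*t) - 1)``.

    ``V`` is the steady-state slope, ``A`` and ``lam`` the amplitude and
    rate constant of the lag.  Passes through the origin; approaches the
    linear asymptote ``V*t - A`` for ``lam*t >> 1``.

    Parameters
    ----------
    t : float or array_like
        Time in seconds, non-negative.
    V, A, lam : float
        Model parameters; ``lam`` must be non-negative.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if lam < 0:
        raise ValueError(f"lag rate constant must be non-negative, got {lam}")
    out = V * t_arr + A * np.expm1(-lam * t_arr)
    return out if t_arr.ndim else float(out)


def lambda_of_substrate(S, rates: SchemeRates):
    """Observed lag rate constant under fast binding.

    ``lambda(S) = k1 + k_minus1 / (Ka*S + 1)``; strictly decreasing in S
    whenever ``k_minus1 > 0`` and ``Ka > 0``.

    Parameters
    ----------
    S : float or array_like
        Free substrate concentration, molar, non-negative.
    rates : SchemeRates
        Must define ``k1``, ``k_minus1`` and ``Ka``.
    """
    if rates.Ka is None:
        raise ValueError("rates.Ka (or k2 and k_minus2) is required")
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("substrate concentration must be non-negative")
    out = rates.k1 + rates.k_minus1 / (rates.Ka * S_arr + 1.0)
    return out if S_arr.ndim else float(out)


def delta_g_from_rates(
    rates: SchemeRates,
    consts: PhysicalConstants = PhysicalConstants(),
    method: str = "delta",
    n_mc: int = 100_000,
    seed: int | None = 0,
) -> StabilityResult:
    """Folding free energy from the folding/unfolding rate constants.

    ``delta_g = R*T*ln(k_minus1 / k1)``: positive when unfolding is
    faster than folding.  If the rates carry standard errors the
    uncertainty is propagated, either first-order (``method="delta"``) or
    by Monte Carlo over truncated-Gaussian rate draws (``method="mc"``).
    """
    if rates.k1 <= 0 or rates.k_minus1 <= 0:
        raise ValueError("k1 and k_minus1 must be positive to compute a free energy")
    dg = consts.RT * math.log(rates.k_minus1 / rates.k1)

    uncertainty = None
    if rates.k1_err is not None and rates.k_minus1_err is not None:
        if method == "delta":
            uncertainty = consts.RT * math.hypot(
                rates.k1_err / rates.k1, rates.k_minus1_err / rates.k_minus1
            )
        elif method == "mc":
            rng = np.random.default_rng(seed)
            k1s = rng.normal(rates.k1, rates.k1_err, n_mc)
            km1s = rng.normal(rates.k_minus1, rates.k_minus1_err, n_mc)
            ok = (k1s > 0) & (km1s > 0)
            uncertainty = float(np.std(consts.RT * np.log(km1s[ok] / k1s[ok]), ddof=1))
        else:
            raise ValueError(f"unknown propagation method {method!r}")
    return StabilityResult(dg, consts.T, "rates", uncertainty)


def delta_g_ligand_shift(delta_g0, S, Km: float, consts: PhysicalConstants = PhysicalConstants()):
    """Ligand-linkage shift of the folding free energy.

    ``delta_g(S) = delta_g0 - R*T*ln(1 + S/Km)``: a ligand binding only
    the folded state stabilizes it, monotonically in ``S``.

    Parameters
    ----------
    delta_g0 : float
        Free energy at zero ligand, kcal mol^-1.
    S : float or array_like
        Ligand concentration, molar, non-negative.
    Km : float
        Ligand Michaelis (binding) constant, molar, positive.
    """
    if Km <= 0 or not math.isfinite(Km):
        raise ValueError(f"Km must be positive and finite, got {Km}")
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("ligand concentration must be non-negative")
    out = delta_g0 - consts.RT * np.log1p(S_arr / Km)
    return out if S_arr.ndim else float(out)


def destabilization(
    delta_g_cage: StabilityResult,
    delta_g_bulk: StabilityResult,
    allow_temperature_mismatch: bool = False,
    temperature_tol: float = 0.5,
) -> StabilityResult:
    """Cage-minus-bulk folding free energy difference.

    Both inputs must be at the same temperature (within
    ``temperature_tol`` kelvin) unless ``allow_temperature_mismatch`` is
    set.  Uncertainties combine in quadrature when both are present.
    """
    dT = abs(delta_g_cage.temperature - delta_g_bulk.temperature)
    if dT > temperature_tol and not allow_temperature_mismatch:
        raise ValueError(
            f"temperature mismatch of {dT:.2f} K between stability results; "
            "pass allow_temperature_mismatch=True to override"
        )
    ddg = delta_g_cage.delta_g - delta_g_bulk.delta_g
    unc = None
    if delta_g_cage.uncertainty is not None and delta_g_bulk.uncertainty is not None:
        unc = math.hypot(delta_g_cage.uncertainty, delta_g_bulk.uncertainty)
    # difference carries the cage result's provenance label
    return StabilityResult(ddg, delta_g_cage.temperature, delta_g_cage.source, unc)
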