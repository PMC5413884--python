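"""Michaelis–Menten kinetics, unit conversions and the biphasic correction.

Initial-rate data v(S) are fitted to v = vmax*S/(Km+S) by non-linear least
squares with multi-start initialisation. Helper conversions derive the
turnover number from a specific activity, the catalytic efficiency kcat/Km,
catalyst loading in mol%, and initial rates from photometric slopes via
Beer–Lambert.

For cyanohydrin synthesis in a two-phase (aqueous/organic) reactor the enzyme
sees only the aqueous substrate pool. With partition coefficient
P = C_org/C_aq, mass balance C_aq*V_aq + P*C_aq*V_org = n_total gives the
de-facto aqueous concentration C_aq = n_total / (V_aq + P*V_org).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RateDataset",
    "KineticFit",
    "BiphasicSystem",
    "FitError",
    "michaelis_menten",
    "fit_michaelis_menten",
    "kcat_from_vmax",
    "vmax_from_kcat",
    "catalytic_efficiency",
    "aqueous_concentration",
    "catalyst_loading",
    "rate_from_absorbance",
    "mandelonitrile_grid",
]


class FitError(RuntimeError):
    """Raised when the non-linear fit fails or lands on a parameter bound."""


@dataclass
class RateDataset:
    """Initial rates at a series of substrate concentrations.

    concentrations_mm: substrate concentrations (mM), rates: observed initial
    rates in any consistent unit (typically µmol·min⁻¹·mg⁻¹).
    """

    concentrations_mm: Sequence[float]
    rates: Sequence[float]
    enzyme_mg: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.concentrations_mm, dtype=float)
        v = np.asarray(self.rates, dtype=float)
        if s.shape != v.shape:
            raise ValueError("concentrations and rates differ in length")
        if np.any(s < 0):
            raise ValueError("substrate concentrations must be non-negative")
        if len(np.unique(s)) < 4:
            raise ValueError(
                "at least 4 distinct substrate concentrations are required for fitting"
            )
        self.concentrations_mm = s
        self.rates = v


@dataclass(frozen=True)
class KineticFit:
    km_mm: float
    vmax: float
    km_se: float
    vmax_se: float
    r_squared: float
    converged: bool
    n_points: int
    kcat_s: float | None = None
    efficiency: float | None = None  # kcat/Km, s⁻¹·mM⁻¹


def michaelis_menten(s, vmax: float, km: float):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def mandelonitrile_grid(n: int = 12) -> np.ndarray:
    """Two-fold dilution series from 18 mM down to ~0.009 mM, the substrate
    range used for mandelonitrile cleavage kinetics."""
    return 18.0 / 2 ** np.arange(n)


def fit_michaelis_menten(
    data: RateDataset,
    weighted: bool = False,
    molar_mass_kda: float | None = None,
) -> KineticFit:
    """Least-squares Michaelis–Menten fit with multi-start initialisation.

    Km is started from the minimum (nonzero), median and maximum substrate
    concentration and the best-SSE solution is kept; standard errors come from
    the curvature (covariance) of the fit. A fit that does not converge, or
    whose Km collapses onto a bound, raises :class:`FitError` rather than
    returning silent estimates. With ``weighted`` the residuals are scaled by
    the observed rates (relative weighting). When ``molar_mass_kda`` is given,
    kcat and kcat/Km are derived (vmax must then be in µmol·min⁻¹·mg⁻¹).
    """
    s = np.asarray(data.concentrations_mm, dtype=float)
    v = np.asarray(data.rates, dtype=float)
    s_pos = s[s > 0]
    if s_pos.size == 0:
        raise ValueError("all substrate concentrations are zero")
    vmax0 = float(np.max(v)) if np.max(v) > 0 else 1.0
    starts = [float(np.min(s_pos)), float(np.median(s_pos)), float(np.max(s_pos))]
    sigma = np.where(v != 0, np.abs(v), np.max(np.abs(v)) or 1.0) if weighted else None

    best = None
    for km0 in starts:
        try:
            popt, pcov = curve_fit(
                michaelis_menten,
                s,
                v,
                p0=[vmax0, km0],
                sigma=sigma,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((v - michaelis_menten(s, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise FitError("Michaelis–Menten fit did not converge from any start")
    sse, popt, pcov = best
    vmax_hat, km_hat = float(popt[0]), float(popt[1])
    # a Km far below or far beyond the probed concentration range is not
    # identifiable from the data (the fit collapsed onto a bound)
    if km_hat < 1e-3 * float(np.min(s_pos)) or km_hat > 1e3 * float(np.max(s_pos)):
        raise FitError(
            f"fitted Km ({km_hat:.3g} mM) lies outside the identifiable range "
            f"of the probed concentrations"
        )
    if vmax_hat <= 0:
        raise FitError("fitted vmax is non-positive")
    perr = np.sqrt(np.diag(pcov))
    ss_tot = float(np.sum((v - np.mean(v)) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else float("nan")
    kcat = eff = None
    if molar_mass_kda is not None:
        kcat = kcat_from_vmax(vmax_hat, molar_mass_kda)
        eff = catalytic_efficiency(kcat, km_hat)
    return KineticFit(
        km_mm=km_hat,
        vmax=vmax_hat,
        km_se=float(perr[1]),
        vmax_se=float(perr[0]),
        r_squared=r2,
        converged=True,
        n_points=len(s),
        kcat_s=kcat,
        efficiency=eff,
    )


def kcat_from_vmax(vmax_umol_min_mg: float, molar_mass_kda: float) -> float:
    """Turnover number (s⁻¹) from specific activity.

    µmol·min⁻¹·mg⁻¹ × kDa (= mg·µmol⁻¹) gives min⁻¹; dividing by 60 gives s⁻¹.
    """
    if molar_mass_kda <= 0:
        raise ValueError("molar mass must be positive")
    if vmax_umol_min_mg < 0:
        raise ValueError("vmax must be non-negative")
    return vmax_umol_min_mg * molar_mass_kda / 60.0


def vmax_from_kcat(kcat_s: float, molar_mass_kda: float) -> float:
    """Inverse of :func:`kcat_from_vmax` (unit round-trip)."""
    if molar_mass_kda <= 0:
        raise ValueError("molar mass must be positive")
    return kcat_s * 60.0 / molar_mass_kda


def catalytic_efficiency(kcat_s: float, km_mm: float) -> float:
    """kcat/Km in s⁻¹·mM⁻¹."""
    if km_mm <= 0:
        raise ValueError("Km must be positive")
    return kcat_s / km_mm


@dataclass(frozen=True)
class BiphasicSystem:
    """An aqueous/organic two-phase reactor at partition equilibrium."""

    aqueous_volume_ml: float
    organic_volume_ml: float
    partition_coefficient: float  # P = C_org / C_aq
    total_substrate_mmol: float

    def __post_init__(self) -> None:
        if self.aqueous_volume_ml <= 0 or self.organic_volume_ml <= 0:
            raise ValueError("phase volumes must be positive")
        if self.partition_coefficient < 0:
            raise ValueError("partition coefficient must be >= 0")


def aqueous_concentration(system: BiphasicSystem) -> float:
    """De-facto aqueous substrate concentration (mmol/mL == M; ×1000 for mM).

    From mass balance C_aq·V_aq + (P·C_aq)·V_org = n_total.
    """
    return system.total_substrate_mmol / (
        system.aqueous_volume_ml
        + system.partition_coefficient * system.organic_volume_ml
    )


def catalyst_loading(
    mass_mg: float, molar_mass_kda: float, substrate_mmol: float
) -> float:
    """Catalyst loading in mol%: enzyme (µmol) over substrate (µmol) × 100.

    kDa equals mg/µmol, so mass_mg / molar_mass_kda is µmol of enzyme.
    """
    if mass_mg <= 0 or molar_mass_kda <= 0 or substrate_mmol <= 0:
        raise ValueError("mass, molar mass and substrate amount must be positive")
    enzyme_umol = mass_mg / molar_mass_kda
    substrate_umol = substrate_mmol * 1000.0
    return 100.0 * enzyme_umol / substrate_umol


def rate_from_absorbance(
    slope_au_per_min: float,
    extinction_mm_cm: float,
    path_cm: float,
    volume_ml: float = 1.0,
    enzyme_mg: float = 1.0,
) -> float:
    """Specific activity (U·mg⁻¹, U = µmol·min⁻¹) from a photometric slope.

    Beer–Lambert: dC/dt (mM·min⁻¹) = slope / (ε · path); multiplying by the
    assay volume in mL gives µmol·min⁻¹. The extinction coefficient is a
    config value (assay wavelength dependent), in mM⁻¹·cm⁻¹.
    """
    if extinction_mm_cm <= 0 or path_cm <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    if volume_ml <= 0 or enzyme_mg <= 0:
        raise ValueError("volume and enzyme amount must be positive")
    dc_dt_mm = slope_au_per_min / (extinction_mm_cm * path_cm)
    umol_per_min = dc_dt_mm * volume_ml
    return umol_per_min / enzyme_mg
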