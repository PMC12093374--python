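"""Growth and conversion kinetics of the two organisms.

The sulfur oxidizer (an *Acidithiobacillus thiooxidans*-type
chemolithoautotroph) grows on a reduced sulfur substrate (H2S or
thiosulfate) with oxygen as electron acceptor.  Its net biomass balance is

    dX/dt = mu_max * gamma * X - k_d * X,
    gamma = [C_LS/(K_S + C_LS)] * [C_LO/(K_O + C_LO)],

a dual-Monod modifier in the dissolved substrate and dissolved oxygen
(product form; a flag switches to the more conservative minimum form).
Substrate oxidation is tied to *gross* growth through the biomass yield;
decay does not return substrate.  Mole ratios to O2, sulfate and protons
come from the stoichiometry registry, independent of kinetics.

The sulfate reducer (a *Desulfovibrio vulgaris*-type anaerobe) uses
dissolved H2 as electron donor:

    r_X = mu_max_S * X * [S/(K_S + S)] * [C_LH/(K_H + C_LH)],
    dX/dt = r_X - k_d * X,      r_S = r_X / Y_S.

Oxidizer concentrations follow the field convention of mg L^-1 for both
biomass and dissolved gases; reducer biomass is g L^-1 and its substrates
mol L^-1.  Conversion rates are returned in mol L^-1 h^-1 so the chemistry
side never sees mass units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .stoichiometry import OXIDATION, REDUCTION


class NonIdentifiabilityWarning(UserWarning):
    """Raised when a calibration dataset cannot pin down the growth rate."""


@dataclass(frozen=True)
class OxidizerParams:
    mu_max: float = 0.05          # h^-1, maximum specific growth rate
    k_d: float = 1.0e-3           # h^-1, decay rate
    k_s: float = 1.0              # mg L^-1, reduced-sulfur half saturation
    k_o: float = 0.5              # mg L^-1, oxygen kinetic constant
    yield_mg_per_mg: float = 0.05  # mg biomass per mg substrate oxidized
    maintenance: float = 0.0      # mg substrate (mg biomass)^-1 h^-1, off
    monod_form: str = "product"   # or "minimum"

    def __post_init__(self):
        for name in ("mu_max", "k_d", "k_s", "k_o", "yield_mg_per_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ReducerParams:
    mu_max_s: float = 0.06        # h^-1
    k_d: float = 5.0e-4           # h^-1
    k_s_sulfate: float = 1.0e-3   # mol L^-1
    k_h: float = 1.0e-6           # mol L^-1
    y_s: float = 5.0              # g biomass per mol sulfate reduced

    def __post_init__(self):
        for name in ("mu_max_s", "k_d", "k_s_sulfate", "k_h", "y_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BiomassState:
    x_oxidizer: float = 0.0  # mg dry weight L^-1
    x_reducer: float = 0.0   # g L^-1

    def validate(self):
        if self.x_oxidizer < 0 or self.x_reducer < 0:
            raise ValueError("biomass concentrations must be non-negative")
        return self


@dataclass
class GrowthRateResult:
    """Rates of one organism's growth and coupled conversions.

    ``dx_dt`` is in the organism's own biomass unit per litre per hour;
    every chemical rate is mol L^-1 h^-1 with consumption positive in its
    named direction (``proton_rate`` > 0 means protons are *produced*).
    """

    gamma: float
    dx_dt: float
    gross_growth: float
    substrate_rate: float         # substrate consumed
    acceptor_donor_rate: float    # O2 (oxidizer) or H2 (reducer) consumed
    proton_rate: float            # produced (+) / consumed (-)
    sulfate_rate: float           # produced (+) / consumed (-)
    product_rate: float = 0.0     # reduced product formed (reducer only)


def _monod(c, k):
    return c / (k + c) if c > 0.0 else 0.0


def oxidizer_rates(x, c_ls, c_lo, params, cycle_variant="s2o3",
                   growth_modifier=None):
    """Oxidizer growth and conversion rates.

    ``x``, ``c_ls``, ``c_lo`` in mg L^-1 (biomass, substrate, dissolved O2).
    ``growth_modifier`` is an optional multiplicative hook (e.g. a Gompertz
    lag or pH window), called with no arguments pre-bound by the caller; the
    default is the identity.
    """
    if x < 0 or c_ls < 0 or c_lo < 0:
        raise ValueError("oxidizer inputs must be non-negative")
    stoich = OXIDATION[cycle_variant]
    m_s, m_o = _monod(c_ls, params.k_s), _monod(c_lo, params.k_o)
    gamma = min(m_s, m_o) if params.monod_form == "minimum" else m_s * m_o
    if growth_modifier is not None:
        gamma *= growth_modifier()
    gross = params.mu_max * gamma * x               # mg L^-1 h^-1
    dx_dt = gross - params.k_d * x
    sub_mg = gross / params.yield_mg_per_mg + params.maintenance * x * m_s
    sub_mol = sub_mg / (1000.0 * stoich.molar_mass)  # mol L^-1 h^-1
    return GrowthRateResult(
        gamma=gamma, dx_dt=dx_dt, gross_growth=gross,
        substrate_rate=sub_mol,
        acceptor_donor_rate=stoich.o2_consumed * sub_mol,
        proton_rate=stoich.protons_produced * sub_mol,
        sulfate_rate=stoich.sulfate_produced * sub_mol,
    )


def reducer_rates(x, s, c_lh, params, cycle_variant="h2s"):
    """Reducer growth and sulfate-reduction rates.

    ``x`` in g L^-1; ``s`` (sulfate) and ``c_lh`` (dissolved H2) in
    mol L^-1.
    """
    if x < 0 or s < 0 or c_lh < 0:
        raise ValueError("reducer inputs must be non-negative")
    stoich = REDUCTION[cycle_variant]
    gamma = _monod(s, params.k_s_sulfate) * _monod(c_lh, params.k_h)
    r_x = params.mu_max_s * gamma * x               # g L^-1 h^-1
    dx_dt = r_x - params.k_d * x
    r_s = r_x / params.y_s                          # mol SO4 L^-1 h^-1
    return GrowthRateResult(
        gamma=gamma, dx_dt=dx_dt, gross_growth=r_x,
        substrate_rate=r_s,
        acceptor_donor_rate=stoich.h2_consumed * r_s,
        proton_rate=-stoich.protons_consumed * r_s,
        sulfate_rate=-r_s,
        product_rate=stoich.product_produced * r_s,
    )


@dataclass
class CalibrationResult:
    mu_max: float
    residual_norm: float
    interval: tuple          # profile-based ~95% interval on mu_max
    n_observations: int
    profile: Optional[np.ndarray] = None  # (mu, ssr) columns if requested


def calibrate_mu_max(times, observed, model, bounds=(1e-4, 0.5),
                     log_space=True, n_profile=60, keep_profile=False):
    """Least-squares calibration of the maximum specific growth rate.

    ``model(mu)`` must return the simulated biomass at ``times``.  The fit
    minimises the sum of squared residuals, by default on the log scale
    (biomass errors are multiplicative).  The returned interval is a
    profile-objective interval: the range of mu over an ``n_profile``-point
    grid whose SSR stays within an F-type threshold of the minimum — crude
    but honest for a one-parameter fit.
    """
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if times.shape != observed.shape:
        raise ValueError("times and observations must have the same shape")
    if np.any(observed <= 0):
        raise ValueError("observations must be positive")
    n = times.size
    if n < 4:
        warnings.warn(
            f"only {n} observations: growth rate may not be identifiable",
            NonIdentifiabilityWarning, stacklevel=2)
    if n >= 2 and np.ptp(observed) / np.max(observed) < 1e-6:
        warnings.warn("observations are flat: growth rate not identifiable",
                      NonIdentifiabilityWarning, stacklevel=2)

    def ssr(mu):
        sim = np.asarray(model(float(mu)), dtype=float)
        if log_space:
            sim = np.log(np.clip(sim, 1e-300, None))
            obs = np.log(observed)
        else:
            obs = observed
        return float(np.sum((sim - obs) ** 2))

    res = minimize_scalar(ssr, bounds=bounds, method="bounded",
                          options={"xatol": 1e-7})
    mu_hat, ssr_min = float(res.x), float(res.fun)

    # profile-objective interval: walk outward from the optimum until the
    # SSR crosses an F-type threshold, then bisect the crossing
    dof = max(n - 1, 1)
    threshold = ssr_min * (1.0 + 3.84 / dof) + 1e-9 * (1.0 + ssr_min)

    def _edge(direction):
        from scipy.optimize import brentq as _brentq

        limit = bounds[0] if direction < 0 else bounds[1]
        prev = mu_hat
        step = max(1e-6, 0.02 * abs(mu_hat))
        for _ in range(60):
            cur = mu_hat + direction * step
            if (direction < 0 and cur <= limit) or \
                    (direction > 0 and cur >= limit):
                cur = limit
            if ssr(cur) > threshold:
                return float(_brentq(lambda m: ssr(m) - threshold,
                                     min(prev, cur), max(prev, cur),
                                     xtol=1e-9))
            if cur == limit:
                return float(limit)
            prev, step = cur, step * 2.0
        return float(cur)

    interval = (_edge(-1), _edge(+1))
    profile = None
    if keep_profile:
        grid = np.linspace(interval[0], interval[1], n_profile)
        profile = np.column_stack([grid, [ssr(m) for m in grid]])
    return CalibrationResult(
        mu_max=mu_hat, residual_norm=np.sqrt(ssr_min), interval=interval,
        n_observations=n, profile=profile)


__all__ = [
    "OxidizerParams", "ReducerParams", "BiomassState", "GrowthRateResult",
    "CalibrationResult", "NonIdentifiabilityWarning",
    "oxidizer_rates", "reducer_rates", "calibrate_mu_max",
]
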