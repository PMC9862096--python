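"""Exact equilibrium speciation of ligand among water, bilayer and protein sites.

All species concentrations are amounts per total solution volume.  With L_W the
free aqueous ligand, the bilayer pool is L_Lb = KP(W->Lb) L_W V_Lb / V_W, the
free protein is P = P_T / (1 + sum_i beta_i L_W^i), and each occupancy species
is PL_i = beta_i P L_W^i.  The ligand mass balance

    g(L_W) = L_W (1 + KP V_Lb / V_W) + sum_i i beta_i P(L_W) L_W^i - L_T = 0

has a unique root in [0, L_T]: every term of g is non-decreasing in L_W (the
bound-ligand term is a saturating, increasing function of L_W), g(0) = -L_T < 0
and g(L_T) >= 0.  The root is found with bracketed Brent iteration; no
excess-ligand assumption is made anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .binding import BindingModel

_REL_TOL = 1e-13


class SpeciationBracketError(RuntimeError):
    """The mass-balance function did not change sign on [0, l_total]."""


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium concentrations of all species (mol per total volume)."""

    l_water: float
    l_bilayer: float
    p_free: float
    pl: np.ndarray          # PL_1 .. PL_n
    l_total: float
    p_total: float

    @property
    def bound_ligand(self) -> float:
        """Ligand held in the protein pocket, sum_i i * PL_i."""
        i = np.arange(1, self.pl.size + 1)
        return float(np.dot(i, self.pl))

    @property
    def occupied_protein(self) -> float:
        return float(self.pl.sum())

    @property
    def mean_occupancy(self) -> float:
        return self.bound_ligand / self.p_total if self.p_total > 0 else 0.0

    def ligand_balance_error(self) -> float:
        """Relative ligand mass-balance residual (should be ~1e-13)."""
        tot = self.l_water + self.l_bilayer + self.bound_ligand
        return abs(tot - self.l_total) / self.l_total if self.l_total > 0 else abs(tot)

    def protein_balance_error(self) -> float:
        tot = self.p_free + self.occupied_protein
        return abs(tot - self.p_total) / self.p_total if self.p_total > 0 else abs(tot)


def _mass_balance(
    l_w: float, l_total: float, p_total: float, part: float, betas: np.ndarray
) -> float:
    powers = l_w ** np.arange(1, betas.size + 1)
    s0 = float(np.dot(betas, powers))
    s1 = float(np.dot(betas * np.arange(1, betas.size + 1), powers))
    return l_w * (1.0 + part) + p_total * s1 / (1.0 + s0) - l_total


def solve_speciation(
    l_total: float,
    p_total: float,
    kp_w_lb: float,
    v_lb: float,
    model: BindingModel,
    v_w: float = 1.0,
) -> SpeciationState:
    """Solve the coupled partition + multi-site binding mass balance exactly.

    Parameters
    ----------
    l_total, p_total : float
        Total ligand and protein concentrations (M, per total volume).
    kp_w_lb : float
        Water->bilayer partition coefficient (dimensionless).
    v_lb : float
        Bilayer volume fraction.
    model : BindingModel
        Binding polynomial of the protein pocket.
    v_w : float
        Aqueous volume fraction (1 by default; pass the exact value to account
        for the volume excluded by the membrane).
    """
    if l_total < 0 or p_total < 0:
        raise ValueError("l_total and p_total must be non-negative")
    if kp_w_lb < 0 or v_lb < 0 or not v_w > 0:
        raise ValueError("kp_w_lb and v_lb must be non-negative, v_w positive")
    betas = model.betas
    part = kp_w_lb * v_lb / v_w
    if l_total == 0.0:
        return SpeciationState(0.0, 0.0, p_total, np.zeros(model.n_sites), 0.0, p_total)

    g = lambda x: _mass_balance(x, l_total, p_total, part, betas)
    g_lo, g_hi = g(0.0), g(l_total)
    if g_lo > 0 or g_hi < 0:
        raise SpeciationBracketError(
            f"mass balance not bracketed on [0, {l_total:g}]: g(0)={g_lo:g}, "
            f"g(l_total)={g_hi:g}"
        )
    if g_hi == 0.0:
        l_w = l_total
    else:
        l_w = brentq(g, 0.0, l_total, rtol=4 * np.finfo(float).eps, xtol=1e-300)

    powers = l_w ** np.arange(1, betas.size + 1)
    p_free = p_total / (1.0 + float(np.dot(betas, powers)))
    pl = betas * p_free * powers
    return SpeciationState(
        l_water=float(l_w),
        l_bilayer=float(part * l_w),
        p_free=float(p_free),
        pl=pl,
        l_total=float(l_total),
        p_total=float(p_total),
    )


def speciation_polynomial_roots(
    l_total: float,
    p_total: float,
    kp_w_lb: float,
    v_lb: float,
    model: BindingModel,
    v_w: float = 1.0,
) -> np.ndarray:
    """All roots of the cleared-denominator mass-balance polynomial.

    Multiplying g(L_W) by the binding polynomial 1 + sum beta_i L_W^i turns the
    mass balance into a degree-(n+1) polynomial.  This provides an independent
    algebraic route to the admissible root and is used for cross-checks; the
    production path is :func:`solve_speciation`.
    """
    betas = model.betas
    part = kp_w_lb * v_lb / v_w
    n = betas.size
    # coefficients in ascending powers of L_W for:
    # (1+part) L (1 + sum beta_i L^i) + PT sum i beta_i L^i - LT (1 + sum beta_i L^i)
    coeffs = np.zeros(n + 2)
    coeffs[0] = -l_total
    coeffs[1] += 1.0 + part
    for i in range(1, n + 1):
        coeffs[i + 1] += (1.0 + part) * betas[i - 1]
        coeffs[i] += p_total * i * betas[i - 1] - l_total * betas[i - 1]
    return np.polynomial.polynomial.polyroots(coeffs)
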