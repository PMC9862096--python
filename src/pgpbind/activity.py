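"""Observable models: ATPase velocity, IAAP displacement, and apparent baselines.

The speciation state fixes the distribution of the protein over occupancy
species PL_i.  ATPase activity is the occupancy-weighted mean of the per-state
activities V_i (with the free protein contributing the basal V0 = 100%), so
the no-ligand limit returns exactly the basal rate.  IAAP photolabeling probes
the fraction of protein still available for IAAP binding; three availability
scenarios map occupancy to availability, and the bound IAAP follows an exact
(no excess-tracer) 1:1 quadratic because the tracer (~5 nM) is below the
protein concentration (~59 nM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from . import constants as c
from .binding import BindingModel
from .speciation import SpeciationState, solve_speciation

_CLIP_EPS = 1e-9


class AvailabilityScenario(str, Enum):
    """How pocket occupancy by the amphiphile blocks IAAP binding."""

    ANY_BOUND = "any_bound"      # one amphiphile suffices (i >= 1 blocks)
    FULL_ONLY = "full_only"      # only the saturated pocket blocks (i = n)
    ALL_BUT_ONE = "all_but_one"  # i >= n - 1 blocks


@dataclass(frozen=True)
class ActivityProfile:
    """Basal ATPase rate and the per-occupancy rates, in % of basal."""

    vi: np.ndarray
    v0: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "vi", np.asarray(self.vi, float))
        if not np.all(np.isfinite(self.vi)) or not np.isfinite(self.v0):
            raise ValueError("activities must be finite")


@dataclass(frozen=True)
class IAAPAssay:
    """IAAP tracer constants and the availability scenario."""

    iaap_total: float = c.IAAP_TOTAL
    kd_iaap: float = c.IAAP_KD
    scenario: AvailabilityScenario = AvailabilityScenario.ALL_BUT_ONE

    def __post_init__(self) -> None:
        if not (self.iaap_total > 0 and self.kd_iaap > 0):
            raise ValueError("iaap_total and kd_iaap must be strictly positive")
        object.__setattr__(self, "scenario", AvailabilityScenario(self.scenario))


def atpase_velocity(state: SpeciationState, profile: ActivityProfile) -> float:
    """Occupancy-weighted ATPase velocity, % of basal."""
    if not state.p_total > 0:
        raise ValueError("p_total must be positive to define a velocity")
    if profile.vi.size != state.pl.size:
        raise ValueError("activity profile length must match the site count")
    w = np.concatenate(([state.p_free], state.pl)) / state.p_total
    return float(np.dot(w, np.concatenate(([profile.v0], profile.vi))))


def apparent_atpase(
    l_total: np.ndarray | float,
    v0: float,
    v1: float,
    k1: float,
    v2: float | None = None,
    k2: float | None = None,
) -> np.ndarray | float:
    """Conventional total-concentration ATPase model (apparent constants).

    The standard two-site rational function
    V = (v0 + v1 S/k1 + v2 S^2/(k1 k2)) / (1 + S/k1 + S^2/(k1 k2)).
    Omit ``k2`` for the activation-only single-site variant; set ``v2=0`` for
    full inhibition at saturation.
    """
    if not k1 > 0 or (k2 is not None and not k2 > 0):
        raise ValueError("dissociation constants must be strictly positive")
    s = np.asarray(l_total, float)
    num = v0 + v1 * s / k1
    den = 1.0 + s / k1
    if k2 is not None:
        q = s**2 / (k1 * k2)
        num = num + (0.0 if v2 is None else v2) * q
        den = den + q
    out = num / den
    return float(out) if np.isscalar(l_total) else out


def available_protein(state: SpeciationState, scenario: AvailabilityScenario) -> float:
    """Protein concentration still able to bind IAAP, given pocket occupancy."""
    scenario = AvailabilityScenario(scenario)
    n = state.pl.size
    if scenario is AvailabilityScenario.ALL_BUT_ONE and n < 2:
        warnings.warn(
            "all_but_one is undefined for n < 2; falling back to any_bound",
            RuntimeWarning,
            stacklevel=2,
        )
        scenario = AvailabilityScenario.ANY_BOUND
    if scenario is AvailabilityScenario.ANY_BOUND:
        return state.p_free
    if scenario is AvailabilityScenario.FULL_ONLY:
        return state.p_free + float(state.pl[: n - 1].sum())
    return state.p_free + float(state.pl[: n - 2].sum())


def iaap_bound_fraction(assay: IAAPAssay, p_star: float) -> float:
    """Fraction of total IAAP bound to protein, exact 1:1 binding with depletion.

    Root in [0, 1] of x^2 + b x + c with b = -(1 + Kd/I_T + P*/I_T) and
    c = P*/I_T, where x = I_P/I_T.
    """
    if p_star < 0:
        raise ValueError("p_star must be non-negative")
    it = assay.iaap_total
    b = -(1.0 + assay.kd_iaap / it + p_star / it)
    cc = p_star / it
    disc = b * b - 4.0 * cc
    if disc < 0:
        raise ArithmeticError("negative discriminant in IAAP binding quadratic")
    x = (-b - np.sqrt(disc)) / 2.0
    return float(min(max(x, 0.0), 1.0))


def iaap_displacement(ip: float, ip0: float) -> float:
    """Percent displacement of bound IAAP relative to the no-modulator level."""
    if not ip0 > 0:
        raise ValueError("ip0 must be strictly positive")
    if ip < -_CLIP_EPS * ip0 or ip > ip0 * (1.0 + _CLIP_EPS):
        raise ValueError("ip must lie in [0, ip0]")
    return float(min(max(100.0 * (ip0 - ip) / ip0, 0.0), 100.0))


def apparent_competitive(
    l_total: np.ndarray | float, ki: float, assay: IAAPAssay
) -> np.ndarray | float:
    """Conventional competitive-displacement model on total concentrations.

    %inhibition = 100 S / (S + Ki (1 + I_T/Kd_IAAP)); the parenthesis is the
    usual tracer-occupancy correction of the half-displacement point.
    """
    if not ki > 0:
        raise ValueError("ki must be strictly positive")
    s = np.asarray(l_total, float)
    out = 100.0 * s / (s + ki * (1.0 + assay.iaap_total / assay.kd_iaap))
    return float(out) if np.isscalar(l_total) else out


# ---------------------------------------------------------------------------
# Forward dose-response models (shared by the fitting engine and the
# synthetic-data generators; there is a single implementation of the math).
# ---------------------------------------------------------------------------

def atpase_curve(
    l_totals: Sequence[float],
    model: BindingModel,
    profile: ActivityProfile,
    p_total: float,
    kp_w_lb: float,
    v_lb: float,
    v_w: float = 1.0,
) -> np.ndarray:
    """ATPase velocity (% basal) at each total modulator concentration."""
    return np.array(
        [
            atpase_velocity(
                solve_speciation(lt, p_total, kp_w_lb, v_lb, model, v_w=v_w), profile
            )
            for lt in np.asarray(l_totals, float)
        ]
    )


def iaap_curve(
    l_totals: Sequence[float],
    model: BindingModel,
    assay: IAAPAssay,
    p_total: float,
    kp_w_lb: float,
    v_lb: float,
    v_w: float = 1.0,
) -> np.ndarray:
    """IAAP displacement (%) at each total modulator concentration.

    The reference bound level I_P0 uses the fully available protein (no
    modulator); each point runs the full chain speciation -> availability ->
    exact IAAP binding -> displacement.
    """
    ip0 = iaap_bound_fraction(assay, p_total) * assay.iaap_total
    out = np.empty(len(l_totals))
    for j, lt in enumerate(np.asarray(l_totals, float)):
        state = solve_speciation(lt, p_total, kp_w_lb, v_lb, model, v_w=v_w)
        p_star = available_protein(state, assay.scenario)
        ip = iaap_bound_fraction(assay, p_star) * assay.iaap_total
        out[j] = iaap_displacement(ip, ip0)
    return out
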