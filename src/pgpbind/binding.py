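"""Binding polynomial for n equal and independent sites on the protein.

For a binding pocket with n equivalent, non-interacting sites of microscopic
association constant Kb, the stepwise macroscopic constants are
K_i = ((n - i + 1)/i) Kb and the overall (Adair) constants are their running
products, beta_i = C(n, i) Kb^i.  The first overall constant beta_1 = n Kb is
the low-occupancy limit and is what a partition experiment measures:
beta_1 = KP(W->P) * Vbar_P with Vbar_P the protein molar volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from . import constants as c


@dataclass(frozen=True)
class BindingModel:
    """Microscopic and macroscopic constants for n equal independent sites.

    ``betas[i-1]`` holds beta_i (units 1/M^i); ``stepwise[i-1]`` holds K_i (1/M).
    """

    n_sites: int
    kb: float
    kd: float
    betas: np.ndarray
    stepwise: np.ndarray

    @property
    def beta1(self) -> float:
        return float(self.betas[0])


def build_binding_model(n: int, kd: float) -> BindingModel:
    """Construct the binding polynomial from the site count and microscopic Kd."""
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError("n must be an integer >= 1")
    if not kd > 0:
        raise ValueError("kd must be strictly positive")
    kb = 1.0 / kd
    i = np.arange(1, n + 1)
    stepwise = (n - i + 1) / i * kb
    betas = np.array([comb(n, int(k)) * kb**int(k) for k in i], dtype=float)
    return BindingModel(n_sites=int(n), kb=kb, kd=kd, betas=betas, stepwise=stepwise)


def beta1_to_partition(beta1: float, pgp_molar_volume: float = c.PGP_MOLAR_VOLUME) -> float:
    """Water->protein partition coefficient implied by the first Adair constant."""
    if not (beta1 > 0 and pgp_molar_volume > 0):
        raise ValueError("beta1 and pgp_molar_volume must be strictly positive")
    return beta1 / pgp_molar_volume


def partition_to_beta1(kp_w_p: float, pgp_molar_volume: float = c.PGP_MOLAR_VOLUME) -> float:
    """Inverse of :func:`beta1_to_partition`."""
    return kp_w_p * pgp_molar_volume


def estimate_site_count(
    kp_w_p: float, pgp_molar_volume: float = c.PGP_MOLAR_VOLUME, kd: float = 1.0
) -> float:
    """Apparent site count from comparing partition and per-site affinity.

    Under the equal-and-independent-sites approximation n = beta_1/Kb, so an
    estimate of the occupancy capacity of the pocket is
    KP(W->P) * Vbar_P * Kd.  It is a real-valued estimate, not an integer.
    """
    if not (kp_w_p > 0 and pgp_molar_volume > 0 and kd > 0):
        raise ValueError("all inputs must be strictly positive")
    return kp_w_p * pgp_molar_volume * kd
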