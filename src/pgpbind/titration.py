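"""Fitting partition coefficients from fluorescence titrations.

The NBD fluorophore brightens on transfer from water into a membrane, so the
intensity measured while titrating membrane into a fixed amount of amphiphile
follows the two-state partition isotherm

    F(v) = (F_W + F_M * KP * v) / (1 + KP * v)

with v the volume fraction of the partitioning phase, F_W the signal of the
fully aqueous ligand and F_M that of the fully membrane-associated ligand.
KP is fitted as Log10(KP), which enforces positivity and matches the
LogNormal convention used when averaging replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy import stats

from .membrane import MembranePreparation

MEMBRANE_UNITS = ("mg_protein_per_mL", "uM_phospholipid")


@dataclass(frozen=True)
class TitrationDataset:
    """Fluorescence signal versus membrane amount for one amphiphile."""

    membrane_amount: np.ndarray
    signal: np.ndarray
    membrane_unit: str
    amphiphile_id: str = ""
    temperature: float = 37.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "membrane_amount", np.asarray(self.membrane_amount, float))
        object.__setattr__(self, "signal", np.asarray(self.signal, float))
        if self.membrane_unit not in MEMBRANE_UNITS:
            raise ValueError(f"membrane_unit must be one of {MEMBRANE_UNITS}")
        if self.membrane_amount.size != self.signal.size:
            raise ValueError("membrane_amount and signal must have equal length")
        if self.membrane_amount.size < 4:
            raise ValueError("a titration needs at least 4 points")
        if np.any(self.membrane_amount < 0):
            raise ValueError("membrane_amount must be non-negative")

    def volume_fractions(
        self, prep: Optional[MembranePreparation] = None, scenario: str = "all_proteins"
    ) -> np.ndarray:
        """Convert the membrane amounts to volume fractions of the sampled phase.

        Phospholipid amounts (model membranes) use the lipid molar volume only;
        protein amounts (native membranes) use the lipid-plus-protein volume of
        the chosen reduction scenario, so the fitted KP is scenario-tagged.
        """
        if self.membrane_unit == "uM_phospholipid":
            lmv = prep.lipid_molar_volume if prep is not None else 0.8
            return self.membrane_amount * 1e-6 * lmv
        if prep is None:
            raise ValueError("a MembranePreparation is required for protein-mass units")
        unit_prep = MembranePreparation(
            protein_conc=1.0,
            pl_protein_mass_ratio=prep.pl_protein_mass_ratio,
            pl_molar_mass=prep.pl_molar_mass,
            lipid_molar_volume=prep.lipid_molar_volume,
            protein_density=prep.protein_density,
            pgp_conc=prep.pgp_conc / prep.protein_conc if scenario == "pgp_only" else 0.0,
            pgp_molar_volume=prep.pgp_molar_volume,
        )
        vf = unit_prep.volume_fractions()
        per_mg = vf.v_lb + (vf.v_p_pgp if scenario == "pgp_only" else vf.v_p_all)
        return self.membrane_amount * per_mg


@dataclass(frozen=True)
class PartitionFit:
    """Result of fitting the partition isotherm to a titration."""

    log_kp: float
    f_water: float
    f_membrane: float
    residual_norm: float
    ci75: tuple[float, float]
    log_kp_stderr: Optional[float]
    scenario: str
    rank_deficient: bool = False

    @property
    def kp(self) -> float:
        return 10.0**self.log_kp


def partition_signal(v: np.ndarray, log_kp: float, f_water: float, f_membrane: float) -> np.ndarray:
    """Two-state partition isotherm evaluated at volume fractions ``v``."""
    kpv = 10.0**log_kp * np.asarray(v, float)
    return (f_water + f_membrane * kpv) / (1.0 + kpv)


def fit_partition_titration(
    data: TitrationDataset,
    prep: Optional[MembranePreparation] = None,
    scenario: str = "all_proteins",
    init: Optional[dict] = None,
) -> PartitionFit:
    """Least-squares fit of (Log10 KP, F_W, F_M) to a fluorescence titration.

    The 75% confidence interval on Log10 KP is covariance-based (Student-t).
    When all points lie in the linear (unsaturated) regime the problem is
    nearly rank-deficient in (KP, F_M); a warning is issued and the interval
    widened accordingly by the inflated standard error.
    """
    v = data.volume_fractions(prep, scenario=scenario)
    y = data.signal
    if np.unique(v).size < 2:
        raise ValueError("titration needs at least two distinct membrane amounts")
    if np.all(v == 0):
        raise ValueError("all membrane amounts are zero")

    params = lmfit.Parameters()
    defaults = _default_init(v, y)
    if init:
        defaults.update(init)
    params.add("log_kp", value=defaults["log_kp"], min=-2.0, max=10.0)
    params.add("f_water", value=defaults["f_water"])
    params.add("f_membrane", value=defaults["f_membrane"])

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return partition_signal(v, p["log_kp"].value, p["f_water"].value, p["f_membrane"].value) - y

    out = lmfit.minimize(residual, params, method="leastsq")
    log_kp = out.params["log_kp"].value
    stderr = out.params["log_kp"].stderr

    # Linear-regime diagnostic: the largest KP*v sampled sets how well the
    # saturation amplitude (and hence KP) is pinned down.
    max_kpv = 10.0**log_kp * float(np.max(v))
    rank_deficient = max_kpv < 0.1
    if rank_deficient:
        warnings.warn(
            "titration points all lie in the linear regime; "
            "KP and F_M are weakly identified and the CI is widened",
            RuntimeWarning,
            stacklevel=2,
        )
    if stderr is None or not np.isfinite(stderr):
        ci = (-np.inf, np.inf)
        stderr = None
    else:
        dof = max(y.size - 3, 1)
        t = stats.t.ppf(0.5 + 0.75 / 2.0, dof)
        ci = (log_kp - t * stderr, log_kp + t * stderr)
    return PartitionFit(
        log_kp=float(log_kp),
        f_water=float(out.params["f_water"].value),
        f_membrane=float(out.params["f_membrane"].value),
        residual_norm=float(np.sqrt(out.chisqr)),
        ci75=ci,
        log_kp_stderr=stderr,
        scenario=scenario if data.membrane_unit == "mg_protein_per_mL" else "lipid_only",
        rank_deficient=bool(rank_deficient),
    )


def _default_init(v: np.ndarray, y: np.ndarray) -> dict:
    order = np.argsort(v)
    f_water = float(y[order][0])
    f_membrane = float(y[order][-1])
    v_pos = v[v > 0]
    # start KP where half-saturation sits mid-range of the sampled fractions
    log_kp = float(-np.log10(np.median(v_pos)))
    return {"log_kp": log_kp, "f_water": f_water, "f_membrane": f_membrane}
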