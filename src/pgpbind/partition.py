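"""Partition-coefficient bookkeeping between water, lipid bilayer and protein.

The whole-membrane partition coefficient measured against native membranes
mixes two sinks: the lipid bilayer and the membrane proteins.  With the
membrane volume split into its lipid and protein parts, the water->protein
coefficient follows from the volume-weighted closure

    KP(W->M) * V_M = KP(W->P) * V_P + KP(W->Lb) * V_Lb,   V_M = V_Lb + V_P

and the bilayer->protein coefficient from the thermodynamic cycle
KP(Lb->P) = KP(W->P) / KP(W->Lb).  In the dilute-ligand limit the ligand
distributes among the media in proportion to KP * V of each medium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .membrane import MembranePreparation

SCENARIOS = ("pgp_only", "all_proteins")


@dataclass(frozen=True)
class AmphiphileRecord:
    """Identity and molecular descriptors of one amphiphile."""

    id: str
    clogd: Optional[float] = None
    chain_length: Optional[int] = None
    cac_25c: Optional[float] = None  # critical aggregation concentration, M, 25 C
    charge: int = 0

    def __post_init__(self) -> None:
        if self.cac_25c is not None and not self.cac_25c > 0:
            raise ValueError("cac_25c must be strictly positive when given")
        if self.chain_length is not None and self.chain_length < 0:
            raise ValueError("chain_length must be >= 0")


@dataclass(frozen=True)
class PartitionCoefficientSet:
    """Partition coefficients of one amphiphile between the assay media.

    All coefficients are dimensionless concentration ratios on a volume basis.
    ``scenario`` records which protein volume (P-gp only, or all membrane
    proteins) was used when reducing the whole-membrane titration, because the
    whole-membrane and water->protein values depend on it.  ``log_sd`` is the
    standard deviation of Log10(KP); replicate averaging follows the LogNormal
    convention (mean of Log10 KP).
    """

    kp_w_m: float
    kp_w_lb: float
    kp_w_p: float
    kp_lb_p: float
    scenario: str
    log_sd: Optional[float] = None
    protein_term_clipped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        for name in ("kp_w_m", "kp_w_lb"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.kp_w_p < 0 or self.kp_lb_p < 0:
            raise ValueError("protein partition coefficients must be non-negative")
        expected = self.kp_w_p / self.kp_w_lb
        if not np.isclose(self.kp_lb_p, expected, rtol=1e-9, atol=1e-300):
            raise ValueError(
                "kp_lb_p inconsistent with kp_w_p / kp_w_lb "
                f"({self.kp_lb_p:g} vs {expected:g})"
            )

    @classmethod
    def from_w_values(
        cls,
        kp_w_m: float,
        kp_w_lb: float,
        kp_w_p: float,
        scenario: str,
        log_sd: Optional[float] = None,
        protein_term_clipped: bool = False,
    ) -> "PartitionCoefficientSet":
        return cls(
            kp_w_m=kp_w_m,
            kp_w_lb=kp_w_lb,
            kp_w_p=kp_w_p,
            kp_lb_p=kp_w_p / kp_w_lb,
            scenario=scenario,
            log_sd=log_sd,
            protein_term_clipped=protein_term_clipped,
        )


@dataclass(frozen=True)
class DiluteDistribution:
    """Dilute-limit distribution of a ligand among water, bilayer and protein."""

    frac_water: float
    frac_bilayer: float
    frac_protein: float
    conc_water: float          # M, amount in water per total volume
    conc_bilayer_local: float  # M, local concentration inside the bilayer
    pl_to_ligand: float        # phospholipid : bilayer-associated ligand, mol/mol

    @property
    def frac_membrane(self) -> float:
        return self.frac_bilayer + self.frac_protein


@dataclass(frozen=True)
class AggregationCheck:
    """Result of comparing the aqueous concentration with the CAC."""

    flag: Optional[bool]  # None when the CAC is unknown
    margin: Optional[float]


@dataclass(frozen=True)
class SeriesRegression:
    slope: float
    intercept: float
    r2: float


def close_cycle(
    kp_w_m: float,
    kp_w_lb: float,
    prep: MembranePreparation,
    scenario: str,
    log_sd: Optional[float] = None,
) -> PartitionCoefficientSet:
    """Split a whole-membrane partition coefficient into bilayer and protein parts.

    Solves the volume-weighted closure for KP(W->P) and completes the
    thermodynamic cycle with KP(Lb->P) = KP(W->P)/KP(W->Lb).  If the
    whole-membrane coefficient falls below the bilayer-only prediction the
    protein coefficient is clipped to zero and flagged rather than raising.
    """
    vf = prep.volume_fractions()
    v_p = vf.v_p(scenario)
    if not v_p > 0:
        raise ValueError(f"protein volume fraction for scenario {scenario!r} is zero")
    kp_w_p = (kp_w_m * (vf.v_lb + v_p) - kp_w_lb * vf.v_lb) / v_p
    clipped = False
    if kp_w_p < 0:
        warnings.warn(
            "whole-membrane KP below the bilayer-only prediction; "
            "protein partition coefficient clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        kp_w_p = 0.0
        clipped = True
    return PartitionCoefficientSet.from_w_values(
        kp_w_m=kp_w_m,
        kp_w_lb=kp_w_lb,
        kp_w_p=kp_w_p,
        scenario=scenario,
        log_sd=log_sd,
        protein_term_clipped=clipped,
    )


def whole_membrane_kp(kps: PartitionCoefficientSet, prep: MembranePreparation) -> float:
    """Recompose KP(W->M) from a coefficient set (round-trip of the closure)."""
    vf = prep.volume_fractions()
    v_p = vf.v_p(kps.scenario)
    return (kps.kp_w_p * v_p + kps.kp_w_lb * vf.v_lb) / (vf.v_lb + v_p)


def distribute_dilute(
    kps: PartitionCoefficientSet,
    prep: MembranePreparation,
    total_ligand: float,
    exact_water_volume: bool = False,
) -> DiluteDistribution:
    """Distribute a dilute ligand among water, bilayer and protein.

    Far from saturation the amounts in each medium are proportional to
    KP * V of the medium (with KP(W->W) = 1), so the fractions are independent
    of the total concentration.  Concentrations are amounts per total solution
    volume except ``conc_bilayer_local`` which is per bilayer volume.
    """
    if not total_ligand > 0:
        raise ValueError("total_ligand must be strictly positive")
    vf = prep.volume_fractions()
    v_p = vf.v_p(kps.scenario)
    v_w = vf.v_water(exact=exact_water_volume, scenario=kps.scenario)
    weights = np.array([v_w, kps.kp_w_lb * vf.v_lb, kps.kp_w_p * v_p])
    fracs = weights / weights.sum()
    frac_water, frac_bilayer, frac_protein = fracs
    conc_bilayer = frac_bilayer * total_ligand
    return DiluteDistribution(
        frac_water=float(frac_water),
        frac_bilayer=float(frac_bilayer),
        frac_protein=float(frac_protein),
        conc_water=float(frac_water * total_ligand),
        conc_bilayer_local=float(conc_bilayer / vf.v_lb),
        pl_to_ligand=float(vf.pl_conc / conc_bilayer) if conc_bilayer > 0 else float("inf"),
    )


def check_aggregation(record: AmphiphileRecord, conc_water: float) -> AggregationCheck:
    """Flag possible aqueous aggregation by comparing with the 25 C CAC.

    Only flags; no temperature correction is attempted (assays run at 37 C,
    where the CAC is expected to be somewhat higher).
    """
    if conc_water < 0:
        raise ValueError("conc_water must be non-negative")
    if record.cac_25c is None:
        return AggregationCheck(flag=None, margin=None)
    margin = conc_water / record.cac_25c
    return AggregationCheck(flag=margin >= 1.0, margin=margin)


def series_regression(values: Sequence[tuple[float, float]]) -> SeriesRegression:
    """Ordinary least squares of a Log-scale quantity on alkyl-chain length.

    For a homologous series, Log10 KP (or LogD) is linear in the number of
    chain carbons; the slope is the per-methylene increment and the intercept
    characterises the polar-group contribution in that medium.
    """
    if len(values) < 3:
        raise ValueError("series_regression needs at least 3 points")
    n, y = np.asarray(values, dtype=float).T
    if np.unique(n).size < 2:
        raise ValueError("chain lengths must not all be identical")
    res = stats.linregress(n, y)
    return SeriesRegression(slope=float(res.slope), intercept=float(res.intercept), r2=float(res.rvalue**2))
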