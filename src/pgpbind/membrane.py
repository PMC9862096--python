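"""Membrane preparation composition: concentrations and volume fractions.

A native-membrane suspension is described by its total protein mass
concentration, the phospholipid:protein mass ratio, and the molar masses /
densities of the components.  From these the molar phospholipid concentration
and the volume fractions of the lipid bilayer and of the protein pool (all
membrane proteins, or P-gp alone) are derived.  Volume fractions are relative
to the total solution volume; they are small (<~1e-3) in all assay conditions,
so the aqueous volume fraction is approximated as 1 by default, with an exact
option.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import constants as c


class InvalidPreparationError(ValueError):
    """A membrane-preparation field is non-positive or inconsistent."""


@dataclass(frozen=True)
class VolumeFractions:
    """Derived composition of a membrane suspension.

    Attributes
    ----------
    pl_conc : float
        Molar phospholipid concentration (mol/dm^3).
    v_lb : float
        Volume fraction of the lipid bilayer.
    v_p_all : float
        Volume fraction of all membrane proteins.
    v_p_pgp : float
        Volume fraction of P-gp alone.
    """

    pl_conc: float
    v_lb: float
    v_p_all: float
    v_p_pgp: float

    def v_p(self, scenario: str) -> float:
        """Protein volume fraction for a reduction scenario."""
        if scenario == "pgp_only":
            return self.v_p_pgp
        if scenario == "all_proteins":
            return self.v_p_all
        raise ValueError(f"unknown scenario {scenario!r}")

    def v_water(self, exact: bool = False, scenario: str = "all_proteins") -> float:
        """Aqueous volume fraction (1 by default; exact subtracts membrane volume)."""
        if not exact:
            return 1.0
        return 1.0 - self.v_lb - self.v_p(scenario)


@dataclass(frozen=True)
class MembranePreparation:
    """Composition constants of a native-membrane suspension.

    Parameters
    ----------
    protein_conc : float
        Total membrane-protein mass concentration, mg/mL.
    pl_protein_mass_ratio : float
        Phospholipid : protein mass ratio, w/w.
    pl_molar_mass : float
        Mean phospholipid molar mass, g/mol.
    lipid_molar_volume : float
        Phospholipid molar volume, dm^3/mol.
    protein_density : float
        Density assumed for membrane proteins, g/mL.
    pgp_conc : float
        P-gp molar concentration, mol/dm^3.
    pgp_molar_volume : float
        P-gp molar volume, dm^3/mol.
    """

    protein_conc: float
    pl_protein_mass_ratio: float = c.PL_PROTEIN_MASS_RATIO
    pl_molar_mass: float = c.PL_MOLAR_MASS
    lipid_molar_volume: float = c.LIPID_MOLAR_VOLUME
    protein_density: float = c.PROTEIN_DENSITY
    pgp_conc: float = c.ATPASE_PGP_CONC
    pgp_molar_volume: float = c.PGP_MOLAR_VOLUME

    def __post_init__(self) -> None:
        for name in (
            "protein_conc",
            "pl_protein_mass_ratio",
            "pl_molar_mass",
            "lipid_molar_volume",
            "protein_density",
            "pgp_molar_volume",
        ):
            if not getattr(self, name) > 0:
                raise InvalidPreparationError(f"{name} must be strictly positive")
        if self.pgp_conc < 0:
            raise InvalidPreparationError("pgp_conc must be non-negative")
        vf = self.volume_fractions()
        if vf.v_lb >= 1 or vf.v_p_all >= 1 or vf.v_p_pgp >= 1:
            raise InvalidPreparationError("derived volume fractions must be < 1")
        if vf.v_p_pgp > vf.v_p_all * (1 + 1e-12):
            raise InvalidPreparationError(
                "P-gp volume fraction exceeds the total-protein volume fraction"
            )

    def volume_fractions(self) -> VolumeFractions:
        """Molar lipid concentration and volume fractions of each membrane medium."""
        # protein_conc mg/mL == g/dm^3; pl_molar_mass g/mol -> pl_conc in mol/dm^3
        pl_conc = self.protein_conc * self.pl_protein_mass_ratio / self.pl_molar_mass
        v_lb = pl_conc * self.lipid_molar_volume
        # mg/mL divided by g/mL: 1e-3 g per mL of protein over density
        v_p_all = self.protein_conc * 1e-3 / self.protein_density
        v_p_pgp = self.pgp_conc * self.pgp_molar_volume
        return VolumeFractions(pl_conc=pl_conc, v_lb=v_lb, v_p_all=v_p_all, v_p_pgp=v_p_pgp)


def volume_fractions(prep: MembranePreparation) -> VolumeFractions:
    """Functional alias for :meth:`MembranePreparation.volume_fractions`."""
    return prep.volume_fractions()
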