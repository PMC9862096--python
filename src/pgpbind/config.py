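"""Schema-validated analysis configuration (pydantic models).

Unknown keys are rejected everywhere and units are explicit in field names;
concentrations in config files are uM (or mg/mL for protein mass) and are
converted to molar when the domain objects are built.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import constants as c
from .activity import IAAPAssay
from .membrane import MembranePreparation
from .partition import AmphiphileRecord


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreparationConfig(_Strict):
    protein_conc_mg_per_mL: float = Field(gt=0)
    pl_protein_mass_ratio: float = Field(default=c.PL_PROTEIN_MASS_RATIO, gt=0)
    pl_molar_mass_g_per_mol: float = Field(default=c.PL_MOLAR_MASS, gt=0)
    lipid_molar_volume_dm3_per_mol: float = Field(default=c.LIPID_MOLAR_VOLUME, gt=0)
    protein_density_g_per_mL: float = Field(default=c.PROTEIN_DENSITY, gt=0)
    pgp_conc_nM: float = Field(default=6.0, ge=0)
    pgp_molar_volume_dm3_per_mol: float = Field(default=c.PGP_MOLAR_VOLUME, gt=0)

    def build(self) -> MembranePreparation:
        return MembranePreparation(
            protein_conc=self.protein_conc_mg_per_mL,
            pl_protein_mass_ratio=self.pl_protein_mass_ratio,
            pl_molar_mass=self.pl_molar_mass_g_per_mol,
            lipid_molar_volume=self.lipid_molar_volume_dm3_per_mol,
            protein_density=self.protein_density_g_per_mL,
            pgp_conc=self.pgp_conc_nM * 1e-9,
            pgp_molar_volume=self.pgp_molar_volume_dm3_per_mol,
        )


class AmphiphileConfig(_Strict):
    id: str
    clogd: Optional[float] = None
    chain_length: Optional[int] = Field(default=None, ge=0)
    cac_25C_uM: Optional[float] = Field(default=None, gt=0)
    charge: int = 0

    def build(self) -> AmphiphileRecord:
        return AmphiphileRecord(
            id=self.id,
            clogd=self.clogd,
            chain_length=self.chain_length,
            cac_25c=self.cac_25C_uM * 1e-6 if self.cac_25C_uM is not None else None,
            charge=self.charge,
        )


class AssayConfig(_Strict):
    kind: Literal["atpase", "iaap"]
    scenario: Literal["any_bound", "full_only", "all_but_one"] = "all_but_one"
    partition_scenario: Literal["pgp_only", "all_proteins"] = "all_proteins"
    iaap_total_nM: float = Field(default=5.0, gt=0)
    kd_iaap_nM: float = Field(default=412.0, gt=0)
    kp_w_lb: float = Field(gt=0)

    def build_iaap(self) -> IAAPAssay:
        return IAAPAssay(
            iaap_total=self.iaap_total_nM * 1e-9,
            kd_iaap=self.kd_iaap_nM * 1e-9,
            scenario=self.scenario,
        )


class FitConfig(_Strict):
    n_min: int = Field(default=1, ge=1)
    n_max: int = Field(default=5, ge=1)
    weighted: bool = False
    constrain_k1_le_k2: bool = False
    ci_level: float = Field(default=0.75, ge=0.0, lt=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _ordered(self) -> "FitConfig":
        if self.n_max < self.n_min:
            raise ValueError("n_max must be >= n_min")
        return self


class AnalysisConfig(_Strict):
    """Top-level configuration for the end-to-end pipeline."""

    preparation: PreparationConfig
    amphiphile: AmphiphileConfig
    assay: AssayConfig
    fit: FitConfig = Field(default_factory=FitConfig)
    titration_csv: Optional[str] = None
    dose_response_csv: Optional[str] = None
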