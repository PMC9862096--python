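import numpy as np
import pytest

from pgpbind import IAAPAssay, MembranePreparation
from pgpbind import constants as c


@pytest.fixture
def atpase_prep() -> MembranePreparation:
    """Native-membrane suspension at ATPase-assay dilution (0.107 mg/mL, 6 nM P-gp)."""
    return MembranePreparation(protein_conc=0.107, pgp_conc=6e-9)


@pytest.fixture
def iaap_prep() -> MembranePreparation:
    """Native-membrane suspension at IAAP-assay dilution (1.0 mg/mL, 60 nM P-gp)."""
    return MembranePreparation(protein_conc=1.0, pgp_conc=60e-9)


@pytest.fixture
def iaap_assay() -> IAAPAssay:
    return IAAPAssay(iaap_total=5e-9, kd_iaap=412e-9)


@pytest.fixture
def table_kp():
    return c.TABLE_KP
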