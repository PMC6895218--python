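import numpy as np
import pandas as pd
import pytest

from opdpipe.stages import OocyteStage
from opdpipe.synthetic import (
    SectionFieldSpec,
    StagePopulationSpec,
    simulate_population,
)


@pytest.fixture(scope="session")
def mono_population():
    """Monodisperse spheres: OD = 200 um, k = 1, 1000 per gram, 10 g ovary."""
    spec = [StagePopulationSpec(OocyteStage.VTO, true_opd=1000.0, diameter_mean_um=200.0)]
    return simulate_population(spec, ovary_mass_g=10.0, specific_gravity=1.061, seed=11)


@pytest.fixture(scope="session")
def packed_population():
    """Polydisperse 100-um spheres at a volume fraction near 0.25."""
    spec = [
        StagePopulationSpec(
            OocyteStage.CAO, true_opd=4.5e5, diameter_mean_um=100.0, diameter_cv=0.05
        )
    ]
    return simulate_population(spec, ovary_mass_g=0.002, specific_gravity=1.061, seed=5)


@pytest.fixture()
def field_spec():
    return SectionFieldSpec(
        field_width_um=500.0,
        field_height_um=500.0,
        slab_thickness_um=4.0,
        n_fields=5,
        field_heterogeneity_cv=0.0,
    )


def make_measurements(rows):
    """rows: iterable of (female_id, stage, L, S, through_nucleus)."""
    return pd.DataFrame(
        rows, columns=["female_id", "stage", "L_um", "S_um", "through_nucleus"]
    )


@pytest.fixture()
def measurements_factory():
    return make_measurements
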