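"""Shared fixtures: small, fast synthetic worlds."""

import pytest

from exosite import ConditionSpec, NoiseModel, OpticalConfig, PlateLayout


@pytest.fixture(scope="session")
def optical():
    return OpticalConfig()


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseModel.zero()


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel()


@pytest.fixture
def small_layout():
    """A 2-well, 2-field plate with half-size fields — fast to render."""
    cond = ConditionSpec("stim", site_rate_per_cell=2.5, large_fraction=0.4)
    return PlateLayout(
        wells=(("A1", cond), ("A2", cond)),
        fields_per_well=2,
        cells_per_field=6.0,
        field_shape=(256, 344),
    )


def make_layout(conditions, wells_per_condition=2, fields_per_well=2,
                cells_per_field=6.0, field_shape=(256, 344)):
    wells = []
    i = 0
    for cond in conditions:
        for _ in range(wells_per_condition):
            wells.append((f"W{i}", cond))
            i += 1
    return PlateLayout(
        wells=tuple(wells),
        fields_per_well=fields_per_well,
        cells_per_field=cells_per_field,
        field_shape=field_shape,
    )
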