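import numpy as np
import pytest

from cranioshift.io import VAULT_CODES, MeasurementTable, VariableRegistry


@pytest.fixture(scope="session")
def registry():
    return VariableRegistry.default()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_table(values, mask=None, period=None, codes=None, region="Testland"):
    """Small helper constructing a MeasurementTable from raw arrays."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    codes = tuple(codes) if codes is not None else VAULT_CODES[:p]
    if mask is None:
        mask = np.isnan(values)
    mask = np.asarray(mask, dtype=bool)
    values = values.copy()
    values[mask] = np.nan
    if period is None:
        period = ["pre"] * n
    return MeasurementTable(
        specimen_id=np.array([f"T-{i:03d}" for i in range(n)], dtype=object),
        region=np.full(n, region, dtype=object),
        period=np.asarray(period, dtype=object),
        values=values,
        missing_mask=mask,
        variable_codes=codes,
    )


@pytest.fixture
def small_complete_table(rng):
    """12 specimens x 4 variables, fully observed, positive."""
    vals = rng.normal(loc=[180, 100, 140, 95], scale=4.0, size=(12, 4))
    return make_table(np.abs(vals) + 1.0, period=["pre"] * 6 + ["post"] * 6)
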