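"""Completeness filtering and geometric-mean size adjustment."""

from __future__ import annotations

import logging

import numpy as np

from .io import PERIODS, MeasurementTable

logger = logging.getLogger(__name__)


class ShapeTable(MeasurementTable):
    """Complete table of dimensionless shape variables: each specimen's
    measurements divided by that specimen's geometric mean, so every row
    has geometric mean 1."""

    def validate(self) -> None:
        super().validate()
        if self.missing_mask.any():
            raise ValueError("shape tables must be complete")
        gm = np.exp(np.log(self.values).mean(axis=1))
        if not np.allclose(gm, 1.0, atol=1e-10):
            raise ValueError("row geometric means deviate from 1")


def filter_incomplete(table: MeasurementTable, threshold: float = 0.5) -> MeasurementTable:
    """Drop specimens missing strictly more than ``threshold`` of the
    variables; a row at exactly the threshold is retained. Surviving rows
    are untouched. Removal counts per period are logged."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    frac = table.missing_mask.mean(axis=1)
    keep = frac <= threshold
    if not keep.all():
        dropped = table.period[~keep]
        counts = {p: int((dropped == p).sum()) for p in PERIODS}
        logger.info(
            "completeness filter dropped %d of %d specimens (threshold %.2f): %s",
            int((~keep).sum()), table.n_specimens, threshold, counts,
        )
    return table.subset_rows(np.flatnonzero(keep))


def size_adjust(table: MeasurementTable) -> ShapeTable:
    """Divide each specimen's row by its geometric mean (computed in log
    space), yielding dimensionless shape variables. Requires a complete,
    strictly positive table."""
    if table.missing_mask.any():
        raise ValueError("size adjustment requires a complete table; impute first")
    if (table.values <= 0).any():
        raise ValueError("size adjustment requires strictly positive values")
    log_gm = np.log(table.values).mean(axis=1)
    adjusted = table.values / np.exp(log_gm)[:, None]
    return ShapeTable(
        table.specimen_id.copy(), table.region.copy(), table.period.copy(),
        adjusted, np.zeros_like(table.missing_mask), table.variable_codes,
        extra=None if table.extra is None else table.extra.copy(),
    )
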