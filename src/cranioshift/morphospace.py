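"""Reference-group PCA morphospace and projection of other groups onto it."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ShapeTable

#: Loadings whose absolute value exceeds this are flagged in reports.
DEFAULT_HIGHLIGHT = 0.35


@dataclass
class Morphospace:
    """PCA of a reference group's shape variables.

    ``loadings`` is orthonormal with one principal component per column;
    ``center`` is the reference-group mean. Sign convention: within each
    column the entry of largest magnitude is positive, so axes are
    deterministic (reported signs of individual variables may differ from
    other software by a column-wide flip).
    """

    variable_codes: tuple[str, ...]
    center: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray

    @property
    def percent_variance(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.eigenvalues.sum()

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def axis_names(self) -> list[str]:
        return [f"PC{k + 1}" for k in range(self.n_components)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variable_codes": list(self.variable_codes),
            "center": self.center.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Morphospace":
        payload = json.loads(Path(path).read_text())
        return cls(
            tuple(payload["variable_codes"]),
            np.asarray(payload["center"], dtype=float),
            np.asarray(payload["loadings"], dtype=float),
            np.asarray(payload["eigenvalues"], dtype=float),
        )


@dataclass
class ScoreTable:
    """Principal-component scores with specimen labels."""

    specimen_id: np.ndarray
    region: np.ndarray
    period: np.ndarray
    scores: np.ndarray
    axis_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "specimen_id": self.specimen_id,
            "region": self.region,
            "period": self.period,
        })
        for k, name in enumerate(self.axis_names):
            df[name] = self.scores[:, k]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoreTable":
        axes = [c for c in df.columns if c.startswith("PC")]
        return cls(
            df["specimen_id"].to_numpy(dtype=object),
            df["region"].to_numpy(dtype=object),
            df["period"].to_numpy(dtype=object),
            df[axes].to_numpy(dtype=float), axes,
        )

    def subset_period(self, period: str) -> "ScoreTable":
        idx = np.flatnonzero(self.period == period)
        return ScoreTable(self.specimen_id[idx], self.region[idx],
                          self.period[idx], self.scores[idx], self.axis_names)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-magnitude entry of each is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_pca(pre_shapes: ShapeTable, use_correlation: bool = False) -> Morphospace:
    """Eigendecomposition of the reference (pre-transition) group's shape
    covariance (denominator n-1); set ``use_correlation`` to standardise
    variables first. Requires more rows than variables."""
    x = pre_shapes.values
    n, p = x.shape
    if n < p + 1:
        raise ValueError(
            f"PCA needs at least {p + 1} specimens for {p} variables, got {n}"
        )
    c = np.corrcoef(x, rowvar=False) if use_correlation else np.cov(x, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(c)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    return Morphospace(
        variable_codes=pre_shapes.variable_codes,
        center=x.mean(axis=0),
        loadings=eigvecs,
        eigenvalues=eigvals,
    )


def project(space: Morphospace, shapes: ShapeTable) -> ScoreTable:
    """Score ``shapes`` on the fixed morphospace: ``(x - center) @ loadings``.
    No refitting occurs; variable sets must match exactly (same order)."""
    if tuple(shapes.variable_codes) != tuple(space.variable_codes):
        raise ValueError(
            f"variable mismatch: table has {list(shapes.variable_codes)}, "
            f"space expects {list(space.variable_codes)}"
        )
    scores = (shapes.values - space.center) @ space.loadings
    return ScoreTable(shapes.specimen_id.copy(), shapes.region.copy(),
                      shapes.period.copy(), scores, space.axis_names)


def project_values(space: Morphospace, values: np.ndarray) -> np.ndarray:
    """Score raw shape value arrays (``(..., p)``) on the morphospace."""
    return (values - space.center) @ space.loadings


def loading_report(
    space: Morphospace,
    n_components: int = 2,
    highlight: float = DEFAULT_HIGHLIGHT,
) -> pd.DataFrame:
    """Loadings and percent variance for the leading components, flagging
    loadings whose absolute value exceeds ``highlight``."""
    if n_components > space.n_components:
        raise ValueError("n_components exceeds available components")
    rows = []
    pct = space.percent_variance
    for j, code in enumerate(space.variable_codes):
        row: dict[str, object] = {"variable": code}
        for k in range(n_components):
            loading = space.loadings[j, k]
            row[f"PC{k + 1}"] = loading
            row[f"PC{k + 1}_flag"] = bool(abs(loading) > highlight)
        rows.append(row)
    pct_row: dict[str, object] = {"variable": "%variance"}
    for k in range(n_components):
        pct_row[f"PC{k + 1}"] = pct[k]
        pct_row[f"PC{k + 1}_flag"] = False
    rows.append(pct_row)
    return pd.DataFrame(rows)
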