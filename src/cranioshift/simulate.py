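"""Synthetic craniometric dataset generation.

Draws specimen measurement vectors from a multivariate normal, applies an
optional mean shift to the post-transition group, and deletes cells
completely at random subject to a per-specimen cap. The shipped default
mean vector and covariance are plausible-magnitude synthetic values for a
7-variable cranial vault set — they are not real anthropometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import VAULT_CODES, MeasurementTable

#: Synthetic defaults (mm) for (M1, M5, M8, M9, M11, M12, M17); plausible
#: orders of magnitude only, provenance "synthetic defaults".
DEFAULT_VAULT_MEANS = np.array([182.0, 101.0, 139.0, 96.0, 122.0, 108.0, 133.0])

#: Contrast along which the shifted scenario moves group means: shorter
#: length measurements (M1, M5 negative) with broader mid-vault (M8, M11
#: positive). Unit norm.
BROADENING_CONTRAST = np.array([-1.0, -1.0, 1.0, 0.0, 1.0, 0.0, 0.0]) / 2.0


def default_vault_covariance() -> np.ndarray:
    """Synthetic-default 7x7 covariance (mm^2): an isometric size factor,
    a length-vs-breadth contrast factor, and independent residual noise."""
    size = np.ones(7)
    cov = (
        16.0 * np.outer(size, size)
        + 49.0 * np.outer(BROADENING_CONTRAST, BROADENING_CONTRAST)
        + 2.25 * np.eye(7)
    )
    return cov


@dataclass
class SyntheticSpec:
    """Parameters for one synthetic two-group dataset."""

    n_pre: int
    n_post: int
    mean_pre: np.ndarray
    covariance: np.ndarray
    shift: np.ndarray
    missing_rate: float = 0.0
    max_missing_per_specimen: float = 0.5
    seed: int = 0
    variable_codes: tuple[str, ...] = VAULT_CODES
    region: str = "Synthetica"

    def __post_init__(self) -> None:
        self.mean_pre = np.asarray(self.mean_pre, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)
        p = self.mean_pre.size
        if self.covariance.shape != (p, p) or self.shift.shape != (p,):
            raise ValueError("mean_pre, covariance and shift dimensions disagree")
        if len(self.variable_codes) != p:
            raise ValueError("variable_codes length disagrees with mean_pre")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        try:
            np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive-definite") from exc
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.max_missing_per_specimen <= 1.0:
            raise ValueError("max_missing_per_specimen must lie in [0, 1]")
        if self.n_pre < 3 or self.n_post < 3:
            raise ValueError("need at least 3 specimens per group")


def _draw_positive(rng: np.random.Generator, mean: np.ndarray,
                   cov: np.ndarray, n: int) -> np.ndarray:
    """MVN draws with whole-row redraw (not clipping) of any row containing
    a non-positive value, so the within-support shape stays normal."""
    x = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    bad = np.flatnonzero((x <= 0).any(axis=1))
    while bad.size:
        x[bad] = rng.multivariate_normal(mean, cov, size=bad.size, method="cholesky")
        bad = bad[(x[bad] <= 0).any(axis=1)]
    return x


def _draw_mask(rng: np.random.Generator, n: int, p: int,
               rate: float, cap_cells: int) -> np.ndarray:
    """MCAR Bernoulli mask with rejection of rows exceeding the cap."""
    if rate == 0.0:
        return np.zeros((n, p), dtype=bool)
    mask = rng.random((n, p)) < rate
    bad = np.flatnonzero(mask.sum(axis=1) > cap_cells)
    while bad.size:
        mask[bad] = rng.random((bad.size, p)) < rate
        bad = bad[mask[bad].sum(axis=1) > cap_cells]
    return mask


def generate_dataset(spec: SyntheticSpec) -> MeasurementTable:
    """Generate a reproducible two-group measurement table from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    p = spec.mean_pre.size
    pre = _draw_positive(rng, spec.mean_pre, spec.covariance, spec.n_pre)
    post = _draw_positive(rng, spec.mean_pre + spec.shift, spec.covariance, spec.n_post)
    values = np.vstack([pre, post])
    n = spec.n_pre + spec.n_post
    cap_cells = int(np.floor(spec.max_missing_per_specimen * p))
    mask = _draw_mask(rng, n, p, spec.missing_rate, cap_cells)
    values = values.copy()
    values[mask] = np.nan
    prefix = spec.region[:3].upper()
    ids = np.array([f"{prefix}-{i:04d}" for i in range(n)], dtype=object)
    period = np.array(["pre"] * spec.n_pre + ["post"] * spec.n_post, dtype=object)
    region = np.full(n, spec.region, dtype=object)
    return MeasurementTable(ids, region, period, values, mask,
                            spec.variable_codes)


def shift_along_contrast(covariance: np.ndarray, contrast: np.ndarray,
                         magnitude_sd: float) -> np.ndarray:
    """Mean-shift vector of ``magnitude_sd`` within-group standard
    deviations along a unit-norm contrast direction."""
    contrast = np.asarray(contrast, dtype=float)
    sd_along = float(np.sqrt(contrast @ covariance @ contrast))
    return magnitude_sd * sd_along * contrast


def ukraine_like_scenario(seed: int, shift_sd: float = 1.0,
                          missing_rate: float = 0.05) -> SyntheticSpec:
    """Strongly unbalanced two-group vault scenario (39 pre / 309 post)
    with a ``shift_sd``-SD post-group mean shift along the broadening
    contrast (M8, M11 up; M1, M5 down)."""
    cov = default_vault_covariance()
    return SyntheticSpec(
        n_pre=39, n_post=309,
        mean_pre=DEFAULT_VAULT_MEANS.copy(), covariance=cov,
        shift=shift_along_contrast(cov, BROADENING_CONTRAST, shift_sd),
        missing_rate=missing_rate, max_missing_per_specimen=3.0 / 7.0,
        seed=seed,
    )


def null_scenario(seed: int, missing_rate: float = 0.05) -> SyntheticSpec:
    """Same regime as :func:`ukraine_like_scenario` but with no group shift."""
    return replace(ukraine_like_scenario(seed, missing_rate=missing_rate),
                   shift=np.zeros(7))
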