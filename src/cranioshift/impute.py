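"""Missing-value estimation by likelihood-weighted model averaging over
all predictor-subset linear regressions.

For each target variable, every non-empty subset of the remaining
variables defines a candidate ordinary-least-squares formula, fitted on
the rows complete for target plus predictors. A missing cell is estimated
as the weighted average of the predictions of all *applicable* formulae
(those whose predictors are all observed for that specimen), the weight
of a formula being proportional to its per-observation Gaussian
likelihood at the fit — i.e. proportional to 1 / residual_sd. The
weight-averaged residual standard deviation is retained per cell so the
estimation error can later be resampled.

Weighting convention: formulae are fitted on differing complete-case
counts, so full-sample likelihoods are not comparable across candidates;
the per-observation log-likelihood ``-log(sd) - log(2*pi)/2 - 1/2`` is
used instead, normalised through log-sum-exp. This makes weights
invariant to a global rescaling of the measurement units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .io import MeasurementTable

logger = logging.getLogger(__name__)

#: Relative floor on the residual SD (times the target column SD); keeps a
#: perfect fit on a tiny complete-case set from receiving infinite weight.
SIGMA_FLOOR_SCALE = 1e-8


@dataclass(frozen=True)
class RegressionFormula:
    """One fitted predictor-subset OLS regression for a target variable."""

    target: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray  # aligned with predictors, mm per mm
    residual_sd: float  # unbiased (df = n - k - 1), floored
    n_cases: int
    target_idx: int = field(repr=False, default=-1)
    predictor_idx: tuple[int, ...] = field(repr=False, default=())

    def predict(self, row: np.ndarray) -> float:
        """Predict the target from a full-length measurement row."""
        x = row[list(self.predictor_idx)]
        return float(self.intercept + x @ self.coefficients)


@dataclass
class ImputedTable:
    """A completed measurement table with per-cell estimation uncertainty.

    Observed cells carry their input values exactly and ``cell_sd`` 0;
    imputed cells carry the weighted-average estimate, the weight-averaged
    residual SD, and the list of (formula, weight) pairs that produced it.
    """

    table: MeasurementTable  # completed (no missing cells)
    cell_sd: np.ndarray
    imputed_mask: np.ndarray  # True where the input cell was missing
    provenance: dict[tuple[str, str], list[tuple[RegressionFormula, float]]]

    @property
    def values(self) -> np.ndarray:
        return self.table.values

    def n_imputed(self) -> int:
        return int(self.imputed_mask.sum())

    def subset_period(self, period: str) -> "ImputedTable":
        idx = np.flatnonzero(self.table.period == period)
        sub = self.table.subset_rows(idx)
        ids = set(sub.specimen_id)
        prov = {k: v for k, v in self.provenance.items() if k[0] in ids}
        return ImputedTable(sub, self.cell_sd[idx], self.imputed_mask[idx], prov)


def enumerate_formulae(variable_codes: Sequence[str], target: str) -> list[tuple[str, ...]]:
    """All non-empty predictor subsets for ``target``, ordered by subset
    size then by position of the predictors in ``variable_codes``."""
    if target not in variable_codes:
        raise ValueError(f"target {target!r} not among variables {list(variable_codes)}")
    others = [c for c in variable_codes if c != target]
    out: list[tuple[str, ...]] = []
    for k in range(1, len(others) + 1):
        out.extend(combinations(others, k))
    return out


def fit_formula(
    values: np.ndarray,
    variable_codes: Sequence[str],
    target: str,
    predictors: Sequence[str],
    sigma_floor: float,
) -> RegressionFormula | None:
    """OLS fit of ``target`` on ``predictors`` over complete cases.

    Returns ``None`` (rejection, not an error) when fewer than
    ``len(predictors) + 2`` complete cases exist or the design matrix is
    rank-deficient. ``values`` is the full matrix with NaN at missing
    cells; rows are assumed already in a canonical order.
    """
    codes = list(variable_codes)
    t = codes.index(target)
    pidx = [codes.index(c) for c in predictors]
    cols = [t] + pidx
    complete = ~np.isnan(values[:, cols]).any(axis=1)
    n = int(complete.sum())
    k = len(pidx)
    if n < k + 2:
        return None
    y = values[complete, t]
    X = np.column_stack([np.ones(n), values[np.ix_(complete, pidx)]])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k + 1:
        logger.debug("rejecting rank-deficient formula %s ~ %s", target, predictors)
        return None
    resid = y - X @ beta
    sd = float(np.sqrt(resid @ resid / (n - k - 1)))
    return RegressionFormula(
        target=target, predictors=tuple(predictors),
        intercept=float(beta[0]), coefficients=beta[1:].copy(),
        residual_sd=max(sd, sigma_floor), n_cases=n,
        target_idx=t, predictor_idx=tuple(pidx),
    )


def formula_weights(applicable: Sequence[RegressionFormula]) -> np.ndarray:
    """Normalised per-observation-likelihood weights (proportional to
    1/residual_sd), computed via log-sum-exp."""
    if not applicable:
        raise ValueError("no applicable formulae to weight")
    # constant terms of the Gaussian log-likelihood cancel in normalisation
    ll = np.array([-np.log(f.residual_sd) for f in applicable])
    ll -= ll.max()
    w = np.exp(ll)
    return w / w.sum()


def impute_cell(
    row: np.ndarray,
    row_mask: np.ndarray,
    candidates: Sequence[RegressionFormula],
    specimen_id: str = "?",
) -> tuple[float, float, list[tuple[RegressionFormula, float]]]:
    """Weighted-average estimate for one missing cell of one specimen.

    ``candidates`` is the fitted formula set for the target variable; only
    formulae whose predictors are all observed in ``row`` are applicable.
    Returns (estimate, sd, provenance) where sd is the weight-averaged
    residual SD.
    """
    applicable = [
        f for f in candidates
        if not row_mask[list(f.predictor_idx)].any()
    ]
    if not applicable:
        raise ValueError(
            f"no applicable formula for specimen {specimen_id!r}: every "
            "candidate requires a predictor that is itself missing"
        )
    w = formula_weights(applicable)
    preds = np.array([f.predict(row) for f in applicable])
    sds = np.array([f.residual_sd for f in applicable])
    estimate = float(w @ preds)
    sd = float(w @ sds)
    return estimate, sd, list(zip(applicable, w.tolist()))


def fit_all_formulae(
    values: np.ndarray,
    variable_codes: Sequence[str],
    targets: Sequence[str] | None = None,
) -> dict[str, list[RegressionFormula]]:
    """Fit every candidate predictor subset for each target variable.

    Rejected candidates (too few complete cases, rank deficiency) are
    dropped with a log entry rather than raising.
    """
    col_sd = np.nanstd(values, axis=0, ddof=0)
    out: dict[str, list[RegressionFormula]] = {}
    codes = list(variable_codes)
    for target in (targets if targets is not None else codes):
        t = codes.index(target)
        floor = SIGMA_FLOOR_SCALE * (col_sd[t] if col_sd[t] > 0 else 1.0)
        fitted: list[RegressionFormula] = []
        n_rejected = 0
        for predictors in enumerate_formulae(codes, target):
            f = fit_formula(values, codes, target, predictors, sigma_floor=floor)
            if f is None:
                n_rejected += 1
            else:
                fitted.append(f)
        if n_rejected:
            logger.info("target %s: rejected %d of %d candidate formulae",
                        target, n_rejected, n_rejected + len(fitted))
        out[target] = fitted
    return out


def impute_table(table: MeasurementTable) -> ImputedTable:
    """Estimate every missing cell of ``table``.

    All candidate formulae are fitted once on the pooled table (both
    periods together, maximising complete cases), then each missing cell
    is filled with its weighted-average estimate. Deterministic given the
    table contents: fitting uses rows in sorted specimen-id order, so the
    result does not depend on input row order.
    """
    order = np.argsort(table.specimen_id.astype(str), kind="stable")
    fit_values = table.values[order]
    missing_targets = [
        c for j, c in enumerate(table.variable_codes) if table.missing_mask[:, j].any()
    ]
    formulae = fit_all_formulae(fit_values, table.variable_codes, missing_targets)

    completed = table.values.copy()
    cell_sd = np.zeros_like(completed)
    provenance: dict[tuple[str, str], list[tuple[RegressionFormula, float]]] = {}
    for i, j in np.argwhere(table.missing_mask):
        code = table.variable_codes[j]
        est, sd, prov = impute_cell(
            table.values[i], table.missing_mask[i], formulae[code],
            specimen_id=str(table.specimen_id[i]),
        )
        completed[i, j] = est
        cell_sd[i, j] = sd
        provenance[(str(table.specimen_id[i]), code)] = prov

    out_table = MeasurementTable(
        table.specimen_id.copy(), table.region.copy(), table.period.copy(),
        completed, np.zeros_like(table.missing_mask), table.variable_codes,
        extra=None if table.extra is None else table.extra.copy(),
    )
    return ImputedTable(out_table, cell_sd, table.missing_mask.copy(), provenance)


def resample_imputations(
    imputed: ImputedTable,
    n_draws: int,
    seed: int,
    mode: Literal["averaged", "mixture"] = "averaged",
) -> np.ndarray:
    """Error-resampling draws of the completed value matrix.

    Returns an array of shape ``(n_draws, n_specimens, n_variables)``.
    In ``averaged`` mode each imputed cell is perturbed by
    ``Normal(0, cell_sd)`` around its point estimate; in ``mixture`` mode
    a formula is drawn per replicate with probability equal to its weight
    and noise is added at that formula's residual SD. Observed cells are
    bitwise identical across draws.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    values = imputed.values
    draws = np.broadcast_to(values, (n_draws,) + values.shape).copy()
    cells = np.argwhere(imputed.imputed_mask)
    if cells.size == 0:
        return draws
    if mode == "averaged":
        noise = rng.standard_normal((n_draws, len(cells)))
        for c, (i, j) in enumerate(cells):
            draws[:, i, j] = values[i, j] + imputed.cell_sd[i, j] * noise[:, c]
    elif mode == "mixture":
        codes = imputed.table.variable_codes
        for i, j in cells:
            prov = imputed.provenance[(str(imputed.table.specimen_id[i]), codes[j])]
            w = np.array([p[1] for p in prov])
            preds = np.array([f.predict(values[i]) for f, _ in prov])
            sds = np.array([f.residual_sd for f, _ in prov])
            pick = rng.choice(len(prov), size=n_draws, p=w / w.sum())
            draws[:, i, j] = preds[pick] + sds[pick] * rng.standard_normal(n_draws)
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    return draws
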