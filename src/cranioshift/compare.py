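"""Two-layer resampling comparison of group score distributions.

Per principal-component axis, three statistics (2.5th percentile, median,
97.5th percentile) summarise each group. The larger (post-transition)
group is repeatedly subsampled without replacement down to the smaller
group's size, giving a null distribution of each statistic; the smaller
(pre-transition) group's statistic carries an uncertainty interval
induced by resampling its imputed cells with noise at the regression
residual SDs. An axis is flagged as shifted only when, for all three
statistics, the pre-group estimation-error interval and the central 95%
of the subsampled post distribution fail to overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impute import ImputedTable, resample_imputations
from .morphospace import Morphospace, ScoreTable, project_values

STAT_NAMES: tuple[str, ...] = ("p2.5", "median", "p97.5")
_QUANTILES = np.array([2.5, 50.0, 97.5])


def percentile_summary(scores: np.ndarray) -> np.ndarray:
    """(2.5th percentile, median, 97.5th percentile) of a score vector,
    by linear interpolation between order statistics."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot summarise an empty score vector")
    return np.percentile(scores, _QUANTILES)


def subsample_null(
    post_scores: ScoreTable | np.ndarray,
    n_small: int,
    n_reps: int = 10000,
    seed: int = 0,
    return_indices: bool = False,
):
    """Null distributions of the three statistics under repeated
    subsampling of the post group down to ``n_small`` specimens.

    Each replicate draws ``n_small`` distinct specimens without
    replacement. Returns an array of shape ``(n_reps, 3, n_axes)``
    (statistics ordered as :data:`STAT_NAMES`).
    """
    scores = post_scores.scores if isinstance(post_scores, ScoreTable) else np.asarray(post_scores)
    if scores.ndim == 1:
        scores = scores[:, None]
    n_post = scores.shape[0]
    if n_small > n_post:
        raise ValueError(f"n_small={n_small} exceeds available specimens ({n_post})")
    if n_small < 1 or n_reps < 1:
        raise ValueError("n_small and n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    # uniform random subsets via argsort of iid uniforms, one row per replicate
    idx = rng.random((n_reps, n_post)).argsort(axis=1)[:, :n_small]
    sub = scores[idx]  # (n_reps, n_small, n_axes)
    stats = np.percentile(sub, _QUANTILES, axis=1)  # (3, n_reps, n_axes)
    out = np.transpose(stats, (1, 0, 2))
    return (out, idx) if return_indices else out


def _size_adjust_draws(draws: np.ndarray) -> np.ndarray:
    gm = np.exp(np.log(draws).mean(axis=-1))
    return draws / gm[..., None]


def _positive_draws(imputed: ImputedTable, n_draws: int, seed: int,
                    mode: str) -> np.ndarray:
    """Error-resampling draws with redraw of (vanishingly rare) cells
    pushed non-positive, so the geometric mean stays defined."""
    draws = resample_imputations(imputed, n_draws, seed, mode=mode)
    bad = draws <= 0
    if bad.any():
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        values = np.broadcast_to(imputed.values, draws.shape)
        sds = np.broadcast_to(imputed.cell_sd, draws.shape)
        while bad.any():
            draws[bad] = values[bad] + sds[bad] * rng.standard_normal(int(bad.sum()))
            bad = draws <= 0
    return draws


def pre_error_interval(
    pre_imputed: ImputedTable,
    space: Morphospace,
    n_draws: int = 10000,
    seed: int = 0,
    mode: str = "averaged",
    return_draws: bool = False,
):
    """Central-95% interval of each (axis, statistic) under imputation
    error: perturb imputed cells, size-adjust, project on the fixed
    morphospace, summarise. Returns ``(lo, hi)`` arrays of shape
    ``(3, n_axes)``; degenerate (lo == hi) when nothing was imputed."""
    draws = _positive_draws(pre_imputed, n_draws, seed, mode)
    scores = project_values(space, _size_adjust_draws(draws))  # (D, n, p)
    stats = np.percentile(scores, _QUANTILES, axis=1)  # (3, D, p)
    lo = np.percentile(stats, 2.5, axis=1)
    hi = np.percentile(stats, 97.5, axis=1)
    if return_draws:
        return lo, hi, np.transpose(stats, (1, 0, 2))
    return lo, hi


@dataclass
class ComparisonResult:
    """Per-axis, per-statistic comparison of pre and post score
    distributions, with the axis-level shift flag."""

    axis_names: list[str]
    stat_names: tuple[str, ...]
    pre_value: np.ndarray  # (3, n_axes) point-estimate statistics
    pre_lo: np.ndarray
    pre_hi: np.ndarray
    post_value: np.ndarray  # (3, n_axes) full post-sample statistics
    post_lo: np.ndarray
    post_hi: np.ndarray
    overlap: np.ndarray  # (3, n_axes) bool
    shift_flag: np.ndarray  # (n_axes,) bool
    n_subsamples: int
    n_error_draws: int
    seed: int
    post_replicates: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, axis in enumerate(self.axis_names):
            for s, stat in enumerate(self.stat_names):
                rows.append({
                    "axis": axis, "statistic": stat,
                    "pre_value": self.pre_value[s, k],
                    "pre_error_lo": self.pre_lo[s, k],
                    "pre_error_hi": self.pre_hi[s, k],
                    "post_value": self.post_value[s, k],
                    "post_null_lo": self.post_lo[s, k],
                    "post_null_hi": self.post_hi[s, k],
                    "overlap": bool(self.overlap[s, k]),
                    "shift_flag": bool(self.shift_flag[k]),
                })
        return pd.DataFrame(rows)


def _intervals_overlap(a_lo, a_hi, b_lo, b_hi) -> np.ndarray:
    return ~((a_hi < b_lo) | (b_hi < a_lo))


def compare_groups(
    pre_imputed: ImputedTable,
    post_imputed: ImputedTable,
    space: Morphospace,
    n_subsamples: int = 10000,
    n_error_draws: int = 10000,
    seed: int = 0,
    mode: str = "averaged",
    apply_error_to_post: bool = False,
) -> ComparisonResult:
    """Assemble the full pre/post comparison on a fixed morphospace.

    The post group must be at least as large as the pre group (it is the
    one subsampled down). With ``apply_error_to_post`` each subsampling
    replicate additionally perturbs the post group's imputed cells, so
    both resampling layers act on the post histograms.
    """
    from .preprocess import size_adjust  # local import avoids cycle

    n_pre = pre_imputed.table.n_specimens
    n_post = post_imputed.table.n_specimens
    if n_pre == 0 or n_post == 0:
        raise ValueError("both groups must be non-empty")
    if n_post < n_pre:
        raise ValueError(
            f"post group ({n_post}) must be at least as large as pre ({n_pre})"
        )
    ss = np.random.SeedSequence(seed)
    seed_err, seed_sub, seed_post_err = (int(s.generate_state(1)[0]) for s in ss.spawn(3))

    pre_scores = project_values(space, size_adjust(pre_imputed.table).values)
    post_scores = project_values(space, size_adjust(post_imputed.table).values)

    pre_value = np.percentile(pre_scores, _QUANTILES, axis=0)
    post_value = np.percentile(post_scores, _QUANTILES, axis=0)

    pre_lo, pre_hi = pre_error_interval(
        pre_imputed, space, n_draws=n_error_draws, seed=seed_err, mode=mode
    )

    if apply_error_to_post and post_imputed.n_imputed() > 0:
        post_draws = _positive_draws(post_imputed, n_subsamples, seed_post_err, mode)
        shaped = project_values(space, _size_adjust_draws(post_draws))
        rng = np.random.default_rng(seed_sub)
        idx = rng.random((n_subsamples, n_post)).argsort(axis=1)[:, :n_pre]
        sub = np.take_along_axis(shaped, idx[:, :, None], axis=1)
        replicates = np.transpose(np.percentile(sub, _QUANTILES, axis=1), (1, 0, 2))
    else:
        replicates = subsample_null(post_scores, n_pre, n_subsamples, seed_sub)

    post_lo = np.percentile(replicates, 2.5, axis=0)
    post_hi = np.percentile(replicates, 97.5, axis=0)

    overlap = _intervals_overlap(pre_lo, pre_hi, post_lo, post_hi)
    shift_flag = ~overlap.any(axis=0)

    return ComparisonResult(
        axis_names=space.axis_names, stat_names=STAT_NAMES,
        pre_value=pre_value, pre_lo=pre_lo, pre_hi=pre_hi,
        post_value=post_value, post_lo=post_lo, post_hi=post_hi,
        overlap=overlap, shift_flag=shift_flag,
        n_subsamples=n_subsamples, n_error_draws=n_error_draws, seed=seed,
        post_replicates=replicates,
    )
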