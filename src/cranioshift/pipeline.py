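"""Run configuration and end-to-end orchestration of one analysis.

A run covers one region and one skull element: partition selection,
completeness filtering, imputation, size adjustment, reference-group PCA
with projection of the post group, and the resampled percentile
comparison. Every source of randomness flows from named seeds in the
configuration; no global random state is used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compare import ComparisonResult, compare_groups
from .impute import impute_table
from .io import (MeasurementTable, VariableRegistry, read_measurements,
                 select_partition, write_measurements, write_report,
                 write_scores)
from .morphospace import (Morphospace, ScoreTable, fit_pca, loading_report,
                          project)
from .preprocess import filter_incomplete, size_adjust
from .simulate import generate_dataset, null_scenario, ukraine_like_scenario

logger = logging.getLogger(__name__)

SCENARIOS = ("ukraine_like", "null")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and context."""


@dataclass
class RunConfig:
    """Validated configuration for one analysis run."""

    region: str
    element: str = "vault"
    input: str | None = None
    scenario: str | None = None
    shift_sd: float = 1.0
    missing_rate: float = 0.1
    missing_threshold: float = 0.5
    highlight: float = 0.35
    n_subsamples: int = 10000
    n_error_draws: int = 10000
    seeds: dict = field(default_factory=dict)
    outdir: str = "out"
    correlation_pca: bool = False
    mixture_resampling: bool = False
    apply_error_to_post: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.input is None) == (self.scenario is None):
            raise ValueError("exactly one of 'input' or 'scenario' must be set")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.element not in ("vault", "face"):
            raise ValueError("element must be 'vault' or 'face'")
        if not 0.0 <= self.missing_threshold < 1.0:
            raise ValueError("missing_threshold must lie in [0, 1)")
        if not 0.0 <= self.highlight:
            raise ValueError("highlight threshold must be non-negative")
        if self.n_subsamples < 1 or self.n_error_draws < 1:
            raise ValueError("replicate counts must be >= 1")
        if "compare" not in self.seeds:
            raise ValueError("seeds must include an explicit 'compare' entry")
        if self.scenario is not None and "simulate" not in self.seeds:
            raise ValueError("synthetic runs need an explicit 'simulate' seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)


def version_and_provenance(config: RunConfig) -> str:
    """Package version plus a stable hash of the full configuration."""
    if config is None:
        raise ValueError("a configuration is required")
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    digest = hashlib.sha256(canonical.encode()).hexdigest()[:16]
    return f"cranioshift {__version__} config={digest} seeds={config.seeds}"


@dataclass
class RunResult:
    space: Morphospace
    scores: ScoreTable
    comparison: ComparisonResult
    log: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _load_table(config: RunConfig, registry: VariableRegistry) -> MeasurementTable:
    if config.input is not None:
        return read_measurements(config.input, registry)
    seed = int(config.seeds["simulate"])
    if config.scenario == "ukraine_like":
        spec = ukraine_like_scenario(seed, shift_sd=config.shift_sd,
                                     missing_rate=config.missing_rate)
    else:
        spec = null_scenario(seed, missing_rate=config.missing_rate)
    spec.region = config.region
    return generate_dataset(spec)


def run_analysis(config: RunConfig, write_artifacts: bool = True) -> RunResult:
    """Execute the full analysis for one region/element configuration.

    Writes all tabular artifacts plus a machine-readable run log to
    ``config.outdir`` unless ``write_artifacts`` is False.
    """
    registry = VariableRegistry.default()
    log: dict = {"provenance": version_and_provenance(config),
                 "config": config.to_dict()}
    if config.n_subsamples == 1 or config.n_error_draws == 1:
        logger.warning("replicate count of 1: intervals will be degenerate")
        log["warnings"] = ["single-replicate intervals are degenerate"]

    table = _stage("load")(_load_table)(config, registry)
    log["n_input"] = table.n_specimens

    part = _stage("select_partition")(select_partition)(
        table, registry, config.element, config.region)
    counts_before = {p: int((part.period == p).sum()) for p in ("pre", "post")}

    filtered = _stage("filter_incomplete")(filter_incomplete)(
        part, config.missing_threshold)
    counts_after = {p: int((filtered.period == p).sum()) for p in ("pre", "post")}
    log["counts_before_filter"] = counts_before
    log["counts_after_filter"] = counts_after

    imputed = _stage("impute")(impute_table)(filtered)
    log["n_imputed_cells"] = imputed.n_imputed()

    pre_imp = imputed.subset_period("pre")
    post_imp = imputed.subset_period("post")

    pre_shapes = _stage("size_adjust")(size_adjust)(pre_imp.table)
    all_shapes = _stage("size_adjust")(size_adjust)(imputed.table)

    space = _stage("fit_pca")(fit_pca)(pre_shapes, config.correlation_pca)
    scores = _stage("project")(project)(space, all_shapes)

    mode = "mixture" if config.mixture_resampling else "averaged"
    comparison = _stage("compare")(compare_groups)(
        pre_imp, post_imp, space,
        n_subsamples=config.n_subsamples, n_error_draws=config.n_error_draws,
        seed=int(config.seeds["compare"]), mode=mode,
        apply_error_to_post=config.apply_error_to_post,
    )
    log["shift_flags"] = {a: bool(f) for a, f in
                          zip(space.axis_names, comparison.shift_flag)}

    if write_artifacts:
        _write_artifacts(config, table, imputed, space, scores, comparison, log)
    return RunResult(space, scores, comparison, log)


def _write_artifacts(config, table, imputed, space, scores, comparison, log) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.scenario is not None:
        write_measurements(table, out / "dataset.csv")
    write_measurements(imputed.table, out / "imputed.csv")
    sd_df = imputed.table.to_frame()[["specimen_id", "region", "period"]].copy()
    for j, code in enumerate(imputed.table.variable_codes):
        sd_df[code] = imputed.cell_sd[:, j]
    write_scores(sd_df, out / "cell_sd.csv")
    space.to_json(out / "space.json")
    write_scores(loading_report(space, highlight=config.highlight),
                 out / "loadings.csv")
    write_scores(scores.to_frame(), out / "scores.csv")
    write_report(comparison, out / "comparison.csv")
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    if config.make_plots:
        from .plots import plot_morphospace, plot_statistic_histograms
        plot_morphospace(scores, space, out / "morphospace.png")
        plot_statistic_histograms(comparison, out / "histograms.png")
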