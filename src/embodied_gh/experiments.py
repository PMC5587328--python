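"""Config-driven experiment runners: parameter sweeps and variant studies.

Three study designs are provided:

* :func:`phase_sweep` — coupling x threshold grid of static-variant runs,
  mapping the phase transition between near-silent and saturated activity
  together with avalanche statistics per cell;
* :func:`homeostasis_sweep` — learning-rate x target-rate grid of
  local-homeostasis runs, measuring the attained activity rate, internode
  correlations, and avalanche statistics;
* :func:`variant_study` — repeated runs of each model variant with per-run
  behavioral metrics and all pairwise group contrasts.

Every cell/repeat derives its own seed from the master seed and its grid
position, so results are independent of evaluation order and fully
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from embodied_gh.avalanche import analyze_catalog, detect_avalanches
from embodied_gh.behavior_metrics import compare_groups, compute_run_metrics
from embodied_gh.connectome import Connectome
from embodied_gh.dynamics import ModelConfig, NodeRoles, node_correlation_matrix
from embodied_gh.embodiment import Arena, RunRecord, run_simulation

logger = logging.getLogger(__name__)

__all__ = [
    "SweepSpec",
    "VariantStudySpec",
    "derive_seed",
    "phase_sweep",
    "homeostasis_sweep",
    "variant_study",
    "plot_trajectory",
]

#: metrics contrasted between variants
_STUDY_METRICS = (
    "mean_activity",
    "activity_node_sd",
    "movement_entropy",
    "fractal_dimension",
    "r_wall_activity",
    "r_wall_threshold",
    "r_threshold_activity",
    "threshold_sd",
    "threshold_cv",
)


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-cell/per-repeat seed, independent of run order."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % np.uint32(2**31))


@dataclass
class SweepSpec:
    """A two-axis parameter sweep over ModelConfig fields."""

    axis1_name: str
    axis1_values: list[float]
    axis2_name: str
    axis2_values: list[float]
    epochs_per_cell: int = 5000
    repeats_per_cell: int = 1
    base_config: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.axis1_values or not self.axis2_values:
            raise ValueError("sweep grids must be non-empty")
        if self.epochs_per_cell < 1:
            raise ValueError("epochs_per_cell must be >= 1")
        if self.repeats_per_cell < 1:
            raise ValueError("repeats_per_cell must be >= 1")
        for name in (self.axis1_name, self.axis2_name):
            if not hasattr(self.base_config, name):
                raise ValueError(f"unknown ModelConfig axis {name!r}")


@dataclass
class VariantStudySpec:
    """Repeated-run comparison of model variants."""

    variants: tuple[str, ...] = ("static", "local", "macro", "combined")
    n_repeats: int = 30
    epochs: int = 2000
    base_config: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.variants) < 2:
            raise ValueError("need at least two variants to compare")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2 for statistics")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _avalanche_row(record: RunRecord) -> dict:
    """Avalanche fit summary of a run; NaNs when the fit is undefined."""
    out = {
        "exponent": np.nan,
        "ls_error": np.nan,
        "nll": np.nan,
        "kappa": np.nan,
        "n_cascades": 0,
    }
    try:
        catalog = detect_avalanches(record.activity, record.config.bin_dt)
        out["n_cascades"] = catalog.n_cascades
        fit = analyze_catalog(catalog)
        out.update(exponent=fit.exponent, ls_error=fit.ls_error, nll=fit.nll, kappa=fit.kappa)
    except ValueError as exc:  # too few / degenerate cascades in this cell
        logger.debug("avalanche fit undefined: %s", exc)
    return out


def phase_sweep(
    spec: SweepSpec,
    c: Connectome,
    roles: NodeRoles,
    arena: Arena | None = None,
) -> pd.DataFrame:
    """Static-variant sweep over (coupling, initial_threshold).

    Returns a long-format frame with one row per (cell, repeat): the two
    axis values, repeat index, derived seed, mean activity, and the
    avalanche fit summary.
    """
    allowed = {"coupling", "initial_threshold"}
    if {spec.axis1_name, spec.axis2_name} != allowed:
        raise ValueError(f"phase sweep axes must be {allowed}")
    rows = []
    for i, v1 in enumerate(spec.axis1_values):
        for j, v2 in enumerate(spec.axis2_values):
            for r in range(spec.repeats_per_cell):
                seed = derive_seed(spec.seed, i, j, r)
                config = replace(
                    spec.base_config,
                    **{spec.axis1_name: v1, spec.axis2_name: v2},
                    variant="static",
                    epochs=spec.epochs_per_cell,
                    seed=seed,
                )
                record = run_simulation(c, roles, config, arena)
                row = {
                    spec.axis1_name: v1,
                    spec.axis2_name: v2,
                    "repeat": r,
                    "seed": seed,
                    "mean_activity": float(record.activity.mean()),
                }
                row.update(_avalanche_row(record))
                rows.append(row)
            logger.info("phase sweep cell (%g, %g) done", v1, v2)
    return pd.DataFrame(rows)


def homeostasis_sweep(
    spec: SweepSpec,
    c: Connectome,
    roles: NodeRoles,
    arena: Arena | None = None,
) -> pd.DataFrame:
    """Local-variant sweep over (alpha, rho).

    Per cell: the attained activity rate (time-mean over the final half of
    the run, discounting the adaptation transient), the mean off-diagonal
    node correlation over that window, the avalanche fit, and a divergence
    flag raised when the mean threshold keeps drifting through the final
    half (the target rate is unattainable, e.g. below the spontaneous
    floor).
    """
    allowed = {"alpha", "rho"}
    if {spec.axis1_name, spec.axis2_name} != allowed:
        raise ValueError(f"homeostasis sweep axes must be {allowed}")
    rows = []
    for i, v1 in enumerate(spec.axis1_values):
        for j, v2 in enumerate(spec.axis2_values):
            for r in range(spec.repeats_per_cell):
                seed = derive_seed(spec.seed, i, j, r)
                config = replace(
                    spec.base_config,
                    **{spec.axis1_name: v1, spec.axis2_name: v2},
                    variant="local",
                    epochs=spec.epochs_per_cell,
                    seed=seed,
                )
                record = run_simulation(c, roles, config, arena)
                half = record.epochs // 2
                act = record.activity[half:]
                attained = float(act.mean())
                _, mean_offdiag, _ = node_correlation_matrix(act)
                mean_thr = record.mean_threshold_series
                drift = (mean_thr[-1] - mean_thr[half]) / max(record.epochs - half, 1)
                divergent = bool(config.alpha > 0 and abs(drift) > 0.02 * config.alpha)
                row = {
                    spec.axis1_name: v1,
                    spec.axis2_name: v2,
                    "repeat": r,
                    "seed": seed,
                    "attained_rate": attained,
                    "mean_offdiag_correlation": mean_offdiag,
                    "threshold_drift": float(drift),
                    "divergent": divergent,
                }
                row.update(_avalanche_row(record))
                rows.append(row)
            logger.info("homeostasis sweep cell (%g, %g) done", v1, v2)
    return pd.DataFrame(rows)


def variant_study(
    spec: VariantStudySpec,
    c: Connectome,
    roles: NodeRoles,
    arena: Arena | None = None,
    resolution: int = 1024,
    keep_records: bool = False,
) -> tuple[pd.DataFrame, dict, dict[str, list[RunRecord]]]:
    """Repeated seeded runs per variant plus all pairwise group contrasts.

    Returns the one-row-per-run metrics table, a report dict with a
    pooled-variance t-test per metric per variant pair, and (when
    ``keep_records``) the run records themselves.
    """
    rows = []
    records: dict[str, list[RunRecord]] = {}
    for vi, variant in enumerate(spec.variants):
        kept = []
        for r in range(spec.n_repeats):
            seed = derive_seed(spec.seed, vi, r)
            config = replace(spec.base_config, variant=variant, epochs=spec.epochs, seed=seed)
            record = run_simulation(c, roles, config, arena)
            metrics = compute_run_metrics(record, resolution=resolution)
            rows.append({"variant": variant, "repeat": r, "seed": seed, **metrics.to_dict()})
            if keep_records:
                kept.append(record)
        records[variant] = kept
        logger.info("variant %s: %d runs done", variant, spec.n_repeats)
    table = pd.DataFrame(rows)

    report: dict = {"n_repeats": spec.n_repeats, "epochs": spec.epochs, "contrasts": {}}
    for va, vb in combinations(spec.variants, 2):
        pair = {}
        a_rows = table[table["variant"] == va]
        b_rows = table[table["variant"] == vb]
        for metric in _STUDY_METRICS:
            res = compare_groups(a_rows[metric], b_rows[metric])
            pair[metric] = {
                "t": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "mean_a": float(a_rows[metric].mean()),
                "mean_b": float(b_rows[metric].mean()),
            }
        report["contrasts"][f"{va}_vs_{vb}"] = pair
    return table, report, records


def plot_trajectory(record: RunRecord, path: str | Path, title: str | None = None) -> None:
    """Static PNG of the agent's path through the arena (a convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(record.x, record.y, lw=0.5)
    ax.plot(record.x[0], record.y[0], "go", ms=4, label="start")
    ax.plot(record.x[-1], record.y[-1], "rs", ms=4, label="end")
    ax.set_xlim(0, record.arena.width)
    ax.set_ylim(0, record.arena.height)
    ax.set_aspect("equal")
    ax.set_xlabel("x (world units)")
    ax.set_ylabel("y (world units)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
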