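"""In silico evaluation protocols over infection-matrix ensembles.

Four experiment-design questions are swept, always scoring the normalised
Frobenius reconstruction error against the known quantitative network:

- ``sweep_delta``: how far from equilibrium must the community start for the
  regression to be well conditioned?
- ``sweep_experiment_count``: at a fixed total measurement budget, is it
  better to run one long experiment or many short ones with different
  initial conditions?
- ``sweep_dt_T`` / ``sweep_fixed_budget``: how do the sampling interval Δt
  and the horizon T trade off, and where is the optimal interval when the
  number of measurements is fixed?
- ``sweep_snr``: how quickly does inference degrade with measurement noise?

Every sweep is a pure function of (matrices, design, master seed). Each
(matrix, grid point, replicate) triple draws its own generator from the
master seed through a fixed spawn-key scheme, so grid points are
statistically independent yet bit-reproducible. Per-run failures are
recorded as NaN and listed in ``meta['failures']`` rather than aborting the
sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from numpy.typing import NDArray

from .feasible import ParameterRanges, feasible_parameters
from .model import InfectionMatrix
from .reconstruct import NetworkReconstruction, build_regression, concat_experiments
from .simulate import (
    CommunityTimeSeries,
    ExperimentDesign,
    add_measurement_noise,
    integrate_and_sample,
    perturbed_initial_state,
)

__all__ = [
    "SweepResult",
    "sweep_delta",
    "sweep_experiment_count",
    "sweep_dt_T",
    "sweep_fixed_budget",
    "sweep_snr",
    "plot_sweep",
]

# spawn-key tags keep the seed streams of different roles disjoint
_TAG_PARAMS, _TAG_INIT, _TAG_NOISE = 0, 1, 2


def _rng(master_seed: int | None, *key: int) -> np.random.Generator:
    ss = np.random.SeedSequence(0 if master_seed is None else master_seed, spawn_key=key)
    return np.random.default_rng(ss)


@dataclass
class SweepResult:
    """Per-matrix errors over a grid, with ensemble mean and spread.

    ``per_matrix_errors`` has one row per ensemble matrix and one column per
    grid point; ``mean_error``/``std_error`` are the NaN-aware column
    aggregates and are always re-derivable from the raw table.
    """

    axis_name: str
    grid: list
    per_matrix_errors: NDArray[np.float64]
    mean_error: NDArray[np.float64] = field(init=False)
    std_error: NDArray[np.float64] = field(init=False)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.per_matrix_errors = np.atleast_2d(np.asarray(self.per_matrix_errors, float))
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            self.mean_error = np.nanmean(self.per_matrix_errors, axis=0)
            self.std_error = np.nanstd(self.per_matrix_errors, axis=0)

    @property
    def n_matrices(self) -> int:
        return self.per_matrix_errors.shape[0]

    def argmin(self):
        """Grid value minimising the ensemble mean error."""
        return self.grid[int(np.nanargmin(self.mean_error))]

    def to_frame(self):
        """Tidy table: one row per (matrix, grid point)."""
        import pandas as pd

        rows = []
        for mi in range(self.n_matrices):
            for gi, g in enumerate(self.grid):
                rows.append(
                    {
                        "matrix": mi,
                        self.axis_name: g if np.isscalar(g) else str(g),
                        "error": self.per_matrix_errors[mi, gi],
                    }
                )
        return pd.DataFrame(rows)


def _matrices(ensemble) -> list[InfectionMatrix]:
    return list(ensemble)


def _prepare(
    matrices: Sequence[InfectionMatrix],
    seed: int | None,
    ranges: ParameterRanges | None,
):
    """Feasible parameters and true quantitative network per matrix."""
    out = []
    for mi, M in enumerate(matrices):
        params = feasible_parameters(M, ranges, _rng(seed, _TAG_PARAMS, mi))
        out.append((M, params, params.quantitative_network(M)))
    return out


def sweep_delta(
    ensemble,
    delta_grid: Sequence[float],
    design: ExperimentDesign = ExperimentDesign(),
    seed: int | None = None,
    ranges: ParameterRanges | None = None,
) -> SweepResult:
    """Reconstruction error vs distance of initial conditions from equilibrium.

    At δ = 0 the trajectory sits on the fixed point, the host matrix has
    (numerically) identical columns, and the conditioning warning fires; the
    error is maximal there and decreases as δ grows.
    """
    matrices = _matrices(ensemble)
    prepared = _prepare(matrices, seed, ranges)
    errors = np.full((len(matrices), len(delta_grid)), np.nan)
    failures: list[dict] = []
    for mi, (M, params, truth) in enumerate(prepared):
        for gi, delta in enumerate(delta_grid):
            try:
                rng = _rng(seed, _TAG_INIT, mi, gi)
                init = perturbed_initial_state(params.H_star, params.V_star, delta, rng)
                ts = integrate_and_sample(params, M, init, design.dt_days, design.T_days)
                ts = add_measurement_noise(ts, design.snr_db, _rng(seed, _TAG_NOISE, mi, gi))
                res = NetworkReconstruction(ts).fit()
                errors[mi, gi] = res.error(truth)
            except Exception as exc:  # recorded, not fatal
                failures.append({"matrix": mi, "grid": gi, "error": repr(exc)})
    return SweepResult(
        axis_name="delta",
        grid=list(delta_grid),
        per_matrix_errors=errors,
        meta={"design": design, "seed": seed, "n_matrices": len(matrices), "failures": failures},
    )


def sweep_experiment_count(
    ensemble,
    counts: Sequence[int] = tuple(range(1, 21)),
    design: ExperimentDesign = ExperimentDesign(),
    seed: int | None = None,
    total_columns: int = 960,
    ranges: ParameterRanges | None = None,
) -> SweepResult:
    """Single long experiment vs many short ones at a fixed column budget.

    For ``p`` experiments, ``p`` runs differing only in their
    initial-condition seed contribute their first ``total_columns // p``
    regression columns each (floor division; the realised budget is recorded
    in ``meta['columns_used']``). Implementation note: a pool of
    ``max(counts)`` full-budget runs is simulated once per matrix and
    sliced, which is equivalent because the first columns of a run do not
    depend on its horizon; this also makes ``p = 1`` exactly the
    single-experiment pipeline.
    """
    matrices = _matrices(ensemble)
    prepared = _prepare(matrices, seed, ranges)
    counts = list(counts)
    n_pool = max(counts)
    dt = design.dt_days
    T_full = total_columns * dt
    errors = np.full((len(matrices), len(counts)), np.nan)
    failures: list[dict] = []
    columns_used = [(total_columns // p) * p for p in counts]
    for mi, (M, params, truth) in enumerate(prepared):
        systems = []
        try:
            for k in range(n_pool):
                rng = _rng(seed, _TAG_INIT, mi, k)
                init = perturbed_initial_state(params.H_star, params.V_star, design.delta, rng)
                ts = integrate_and_sample(params, M, init, dt, T_full)
                ts = add_measurement_noise(ts, design.snr_db, _rng(seed, _TAG_NOISE, mi, k))
                systems.append(build_regression(ts))
        except Exception as exc:
            failures.append({"matrix": mi, "grid": None, "error": repr(exc)})
            continue
        for gi, p in enumerate(counts):
            try:
                cols = total_columns // p
                pooled = concat_experiments([systems[k].first_columns(cols) for k in range(p)])
                res = NetworkReconstruction(pooled).fit()
                errors[mi, gi] = res.error(truth)
            except Exception as exc:
                failures.append({"matrix": mi, "grid": gi, "error": repr(exc)})
    return SweepResult(
        axis_name="n_experiments",
        grid=counts,
        per_matrix_errors=errors,
        meta={
            "design": design,
            "seed": seed,
            "n_matrices": len(matrices),
            "total_columns": total_columns,
            "columns_used": columns_used,
            "failures": failures,
        },
    )


def _sweep_design_pairs(
    matrices: Sequence[InfectionMatrix],
    pairs: Sequence[tuple[float, float]],
    design: ExperimentDesign,
    seed: int | None,
    ranges: ParameterRanges | None,
    axis_name: str,
) -> SweepResult:
    from .simulate import HOURS_PER_DAY, MINUTES_PER_DAY

    prepared = _prepare(matrices, seed, ranges)
    errors = np.full((len(matrices), len(pairs)), np.nan)
    failures: list[dict] = []
    for mi, (M, params, truth) in enumerate(prepared):
        for gi, (dt_min, T_hours) in enumerate(pairs):
            try:
                rng = _rng(seed, _TAG_INIT, mi, gi)
                init = perturbed_initial_state(params.H_star, params.V_star, design.delta, rng)
                ts = integrate_and_sample(
                    params, M, init, dt_min / MINUTES_PER_DAY, T_hours / HOURS_PER_DAY
                )
                ts = add_measurement_noise(ts, design.snr_db, _rng(seed, _TAG_NOISE, mi, gi))
                res = NetworkReconstruction(ts).fit()
                errors[mi, gi] = res.error(truth)
            except Exception as exc:
                failures.append({"matrix": mi, "grid": gi, "error": repr(exc)})
    return SweepResult(
        axis_name=axis_name,
        grid=list(pairs),
        per_matrix_errors=errors,
        meta={"design": design, "seed": seed, "n_matrices": len(matrices), "failures": failures},
    )


def sweep_dt_T(
    ensemble,
    dt_grid_min: Sequence[float],
    T_grid_hours: Sequence[float],
    design: ExperimentDesign = ExperimentDesign(),
    seed: int | None = None,
    ranges: ParameterRanges | None = None,
) -> SweepResult:
    """Error surface over sampling interval Δt (minutes) × horizon T (hours).

    Only pairs with ``T ≥ Δt`` are evaluated; the grid entries are
    ``(dt_min, T_hours)`` tuples in row-major (T outer, dt inner) order.
    """
    pairs = [
        (float(dt), float(T))
        for T in T_grid_hours
        for dt in dt_grid_min
        if T * 60.0 >= dt
    ]
    matrices = _matrices(ensemble)
    return _sweep_design_pairs(matrices, pairs, design, seed, ranges, "dt_T")


def sweep_fixed_budget(
    ensemble,
    dt_grid_min: Sequence[float],
    n_measurements: int,
    design: ExperimentDesign = ExperimentDesign(),
    seed: int | None = None,
    ranges: ParameterRanges | None = None,
) -> SweepResult:
    """Fixed-budget slice of the Δt × T surface: T = Δt × n_measurements.

    Along this slice short intervals buy little independent information per
    column while long intervals break the linearisation of the
    log-derivative, so the minimum sits at an intermediate Δt.
    """
    pairs = [(float(dt), float(dt) * n_measurements / 60.0) for dt in dt_grid_min]
    matrices = _matrices(ensemble)
    res = _sweep_design_pairs(matrices, pairs, design, seed, ranges, "dt_fixed_budget")
    res.grid = [dt for dt, _ in pairs]
    res.meta["n_measurements"] = n_measurements
    return res


def sweep_snr(
    ensemble,
    snr_db_grid: Sequence[float],
    design: ExperimentDesign = ExperimentDesign(
        n_experiments=20, T_hours=4.8, dt_min=6.0
    ),
    seed: int | None = None,
    ranges: ParameterRanges | None = None,
) -> SweepResult:
    """Reconstruction error vs measurement signal-to-noise ratio (dB).

    Uses the multi-experiment design (default 20 runs × 48 columns). The
    noiseless trajectories are simulated once per matrix; each SNR grid
    point injects its own independently seeded noise before the regression
    is rebuilt.
    """
    matrices = _matrices(ensemble)
    prepared = _prepare(matrices, seed, ranges)
    snr_db_grid = list(snr_db_grid)
    errors = np.full((len(matrices), len(snr_db_grid)), np.nan)
    failures: list[dict] = []
    for mi, (M, params, truth) in enumerate(prepared):
        clean: list[CommunityTimeSeries] = []
        try:
            for k in range(design.n_experiments):
                rng = _rng(seed, _TAG_INIT, mi, k)
                init = perturbed_initial_state(params.H_star, params.V_star, design.delta, rng)
                clean.append(
                    integrate_and_sample(params, M, init, design.dt_days, design.T_days)
                )
        except Exception as exc:
            failures.append({"matrix": mi, "grid": None, "error": repr(exc)})
            continue
        for gi, snr in enumerate(snr_db_grid):
            try:
                noisy = [
                    add_measurement_noise(ts, snr, _rng(seed, _TAG_NOISE, mi, gi, k))
                    for k, ts in enumerate(clean)
                ]
                res = NetworkReconstruction(noisy).fit()
                errors[mi, gi] = res.error(truth)
            except Exception as exc:
                failures.append({"matrix": mi, "grid": gi, "error": repr(exc)})
    return SweepResult(
        axis_name="snr_db",
        grid=snr_db_grid,
        per_matrix_errors=errors,
        meta={"design": design, "seed": seed, "n_matrices": len(matrices), "failures": failures},
    )


def plot_sweep(result: SweepResult, path=None, ax=None, logy: bool = True):
    """Mean ± std of the error over the sweep grid (1-D grids only)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    grid = result.grid
    if grid and isinstance(grid[0], tuple):
        raise ValueError("plot_sweep handles 1-D grids; slice the surface first")
    x = np.asarray(grid, dtype=float)
    finite = np.isfinite(x)
    ax.errorbar(
        x[finite],
        result.mean_error[finite],
        yerr=result.std_error[finite],
        marker="o",
        capsize=3,
    )
    ax.set_xlabel(result.axis_name)
    ax.set_ylabel("mean reconstruction error")
    if logy:
        ax.set_yscale("log")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
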