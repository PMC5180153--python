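"""Community-dynamics simulation and measurement emulation.

Trajectories are produced by integrating the Lotka-Volterra community model
from initial densities displaced from the engineered equilibrium by a
fraction δ (each population independently at ``x_eq(1+δ)`` or
``x_eq(1−δ)`` with equal probability), then sampling on a regular time
grid. Optionally, measurements are corrupted with additive white Gaussian
noise at a prescribed per-trajectory signal-to-noise ratio.

Internally everything runs in days; :class:`ExperimentDesign` carries the
bench-friendly units (minutes for the sampling interval, hours for the
horizon) and converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import solve_ivp

from .exceptions import DimensionError, IntegrationError
from .model import CommunityState, InfectionMatrix, SystemParameters, ode_rhs

__all__ = [
    "CommunityTimeSeries",
    "ExperimentDesign",
    "perturbed_initial_state",
    "integrate_and_sample",
    "add_measurement_noise",
    "simulate_experiment",
    "MINUTES_PER_DAY",
    "HOURS_PER_DAY",
]

MINUTES_PER_DAY = 1440.0
HOURS_PER_DAY = 24.0


@dataclass
class CommunityTimeSeries:
    """Sampled host and virus trajectories on a regular time grid.

    ``times`` are in days and equally spaced; ``H`` is ``N_h × n_samples``
    and ``V`` is ``N_v × n_samples`` (densities per ml, strictly positive).
    ``meta`` records provenance: seed, δ, sampling interval, horizon, SNR
    and solver tolerances.
    """

    times: NDArray[np.float64]
    H: NDArray[np.float64]
    V: NDArray[np.float64]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        n = self.times.size
        if self.H.shape[1] != n or self.V.shape[1] != n:
            raise DimensionError("H and V must have one column per sample time")
        if n >= 2:
            steps = np.diff(self.times)
            if (steps <= 0).any():
                raise ValueError("sample times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
                raise ValueError("sample times must be equally spaced")

    @property
    def n_hosts(self) -> int:
        return self.H.shape[0]

    @property
    def n_viruses(self) -> int:
        return self.V.shape[0]

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Sampling interval in days."""
        return float(self.times[1] - self.times[0])

    def truncated(self, n_samples: int) -> "CommunityTimeSeries":
        """First ``n_samples`` grid points (provenance carried over)."""
        return CommunityTimeSeries(
            times=self.times[:n_samples].copy(),
            H=self.H[:, :n_samples].copy(),
            V=self.V[:, :n_samples].copy(),
            meta={**self.meta, "truncated_to": n_samples},
        )


@dataclass(frozen=True)
class ExperimentDesign:
    """Measurement protocol for one or more in silico experiments.

    delta : fractional displacement of initial densities from equilibrium.
    dt_min : sampling interval in minutes.
    T_hours : horizon in hours; ``round(T/dt)`` sampling intervals, i.e.
        usable regression columns ("measurements"), plus the t=0 point.
    snr_db : per-trajectory signal-to-noise ratio in dB (``inf`` = noiseless).
    n_experiments : replicate runs differing only in initial conditions.
    """

    delta: float = 0.5
    dt_min: float = 6.0
    T_hours: float = 96.0
    snr_db: float = math.inf
    n_experiments: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.delta < 1):
            raise ValueError("delta must lie in [0, 1): densities must stay positive")
        if self.dt_min <= 0 or self.T_hours * 60.0 < self.dt_min:
            raise ValueError("require dt > 0 and T >= dt")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")

    @property
    def dt_days(self) -> float:
        return self.dt_min / MINUTES_PER_DAY

    @property
    def T_days(self) -> float:
        return self.T_hours / HOURS_PER_DAY

    @property
    def n_measurements(self) -> int:
        """Number of sampling intervals = usable regression columns."""
        return round(self.T_days / self.dt_days)


def perturbed_initial_state(
    H_star: ArrayLike,
    V_star: ArrayLike,
    delta: float,
    seed: int | np.random.Generator | None = None,
) -> CommunityState:
    """Displace each population from equilibrium by a random ±δ fraction.

    Each host and virus density is independently set to ``x_eq(1+δ)`` or
    ``x_eq(1−δ)`` with probability 1/2. ``delta=0`` returns the equilibrium
    exactly; ``delta>=1`` is rejected (non-positive densities).
    """
    if delta < 0 or delta >= 1:
        raise ValueError("delta must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    H_star = np.asarray(H_star, dtype=float).ravel()
    V_star = np.asarray(V_star, dtype=float).ravel()
    signs = rng.integers(0, 2, size=H_star.size + V_star.size) * 2 - 1
    h0 = H_star * (1.0 + delta * signs[: H_star.size])
    v0 = V_star * (1.0 + delta * signs[H_star.size:])
    return CommunityState(h=h0, v=v0)


def integrate_and_sample(
    params: SystemParameters,
    M: InfectionMatrix,
    init: CommunityState,
    dt: float,
    T: float,
    rtol: float = 1e-8,
    atol_scale: float = 1e-8,
    meta: dict[str, Any] | None = None,
) -> CommunityTimeSeries:
    """Integrate the community ODEs and sample at ``t = 0, dt, 2dt, …, T``.

    Uses an adaptive Dormand-Prince Runge-Kutta scheme (RK45) with dense
    output, so the sample grid is exact regardless of the internal steps.
    ``dt`` and ``T`` are in days. Absolute tolerance is scaled per type by
    its equilibrium density (``atol_scale × x_eq``): host and virus
    densities differ by ~3 orders of magnitude and a single absolute
    tolerance would be meaningless for one of them.
    """
    n_h = params.n_hosts
    n_steps = round(T / dt)
    t_eval = np.arange(n_steps + 1) * dt

    def rhs(t: float, y: NDArray) -> NDArray:
        state = CommunityState(y[:n_h], y[n_h:], validate=False)
        d = ode_rhs(state, params, M)
        return np.concatenate([d.h, d.v])

    atol = atol_scale * np.concatenate([params.H_star, params.V_star])
    sol = solve_ivp(
        rhs,
        (0.0, t_eval[-1]),
        np.concatenate([init.h, init.v]),
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    Y = sol.y
    if (Y <= 0).any():
        raise IntegrationError(
            "integrator produced non-positive sampled densities; "
            "tighten tolerances or reduce the perturbation"
        )
    return CommunityTimeSeries(
        times=t_eval,
        H=Y[:n_h],
        V=Y[n_h:],
        meta={
            "dt_days": dt,
            "T_days": T,
            "rtol": rtol,
            "atol_scale": atol_scale,
            **(meta or {}),
        },
    )


def add_measurement_noise(
    ts: CommunityTimeSeries,
    snr_db: float,
    seed: int | np.random.Generator | None = None,
    viruses_only: bool = False,
    clip_floor_frac: float = 1e-6,
) -> CommunityTimeSeries:
    """Corrupt sampled densities with additive white Gaussian noise.

    For each trajectory (each host and each virus series) independently, the
    noise variance is ``σ² = P_signal / 10^(snr_db/10)`` with ``P_signal``
    the mean squared density of that series, so the requested SNR holds per
    series in power. Non-positive noisy values are clipped to
    ``clip_floor_frac × min(series)`` so downstream logarithms stay finite.
    ``snr_db = inf`` returns an identical copy.
    """
    if math.isinf(snr_db):
        return CommunityTimeSeries(
            times=ts.times.copy(),
            H=ts.H.copy(),
            V=ts.V.copy(),
            meta={**ts.meta, "snr_db": math.inf},
        )
    rng = np.random.default_rng(seed)
    ratio = 10.0 ** (snr_db / 10.0)

    def corrupt(X: NDArray) -> NDArray:
        sigma = np.sqrt((X**2).mean(axis=1) / ratio)
        noisy = X + rng.normal(0.0, 1.0, size=X.shape) * sigma[:, None]
        floor = clip_floor_frac * X.min(axis=1)
        return np.where(noisy <= 0, floor[:, None], noisy)

    H = ts.H.copy() if viruses_only else corrupt(ts.H)
    V = corrupt(ts.V)
    return CommunityTimeSeries(
        times=ts.times.copy(),
        H=H,
        V=V,
        meta={**ts.meta, "snr_db": snr_db, "clip_floor_frac": clip_floor_frac},
    )


def simulate_experiment(
    params: SystemParameters,
    M: InfectionMatrix,
    design: ExperimentDesign,
    seed: int | np.random.Generator | None = None,
    rtol: float = 1e-8,
    atol_scale: float = 1e-8,
) -> CommunityTimeSeries:
    """One full experiment: perturb, integrate, sample, add noise.

    ``seed`` overrides ``design.seed``; the initial-condition signs and the
    measurement noise are drawn from the same seeded stream in that order.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    init = perturbed_initial_state(params.H_star, params.V_star, design.delta, rng)
    ts = integrate_and_sample(
        params,
        M,
        init,
        design.dt_days,
        design.T_days,
        rtol=rtol,
        atol_scale=atol_scale,
        meta={"delta": design.delta, "dt_min": design.dt_min, "T_hours": design.T_hours},
    )
    return add_measurement_noise(ts, design.snr_db, rng)
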