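"""Feasibility-based parameter generation.

Rather than screening random rate constants for coexistence, the generator
*engineers* a positive equilibrium: adsorption rates, burst sizes and target
equilibrium densities are drawn from uniform ranges, and the host growth
rates ``r`` and viral decay rates ``m`` are then obtained by solving the
steady-state equations, so that the target densities ``(H*, V*)`` are an
exact fixed point of the dynamics.

At steady state the virus equation gives, per virus ``j``,

    m_j = Σ_i M_ij β_ij φ_ij H*_i

and the host equation gives, per host ``i``,

    r_i = (Σ_j M_ij φ_ij V*_j) / (1 − Σ_i' a_ii' H*_i' / K).

Both are strictly positive exactly when every virus has at least one host,
every host at least one virus, and the competition-weighted equilibrium
load stays below the carrying capacity.

Default ranges (uniform): adsorption rate φ_j in [1e-8, 1e-7] ml/(virus·d),
burst size β_j in [10, 50] viruses/cell, host equilibria H*_i in [1e3, 1e4]
cells/ml, virus equilibria V*_j in [1e6, 1e7] virus/ml, and carrying
capacity K = 100 × max_i H*_i. φ and β are drawn once per *virus* and
broadcast across hosts; per-pair matrices are accepted for generality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .exceptions import FeasibilityError
from .model import InfectionMatrix, SystemParameters

__all__ = [
    "ParameterRanges",
    "sample_ranges",
    "derive_growth_and_decay",
    "feasible_parameters",
]


@dataclass(frozen=True)
class ParameterRanges:
    """Uniform sampling intervals for the free model parameters."""

    phi_range: tuple[float, float] = (1e-8, 1e-7)
    beta_range: tuple[float, float] = (10.0, 50.0)
    H_star_range: tuple[float, float] = (1e3, 1e4)
    V_star_range: tuple[float, float] = (1e6, 1e7)
    K_multiplier: float = 100.0

    def __post_init__(self) -> None:
        for name in ("phi_range", "beta_range", "H_star_range", "V_star_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high, got ({lo}, {hi})")
        if self.K_multiplier <= 0:
            raise ValueError("K_multiplier must be positive")


@dataclass
class SampledRates:
    """Free parameters drawn from :class:`ParameterRanges` (r and m pending)."""

    phi: NDArray[np.float64]  # (n_h, n_v)
    beta: NDArray[np.float64]  # (n_h, n_v)
    H_star: NDArray[np.float64]
    V_star: NDArray[np.float64]
    K: float
    meta: dict[str, Any] = field(default_factory=dict)


def sample_ranges(
    ranges: ParameterRanges,
    n_h: int,
    n_v: int,
    seed: int | np.random.Generator | None = None,
) -> SampledRates:
    """Draw per-virus φ, β and per-type equilibrium targets; set K.

    φ_j and β_j are constant down each column (one value per virus).
    K is ``K_multiplier × max_i H*_i``.
    """
    rng = np.random.default_rng(seed)
    phi_v = rng.uniform(*ranges.phi_range, size=n_v)
    beta_v = rng.uniform(*ranges.beta_range, size=n_v)
    H_star = rng.uniform(*ranges.H_star_range, size=n_h)
    V_star = rng.uniform(*ranges.V_star_range, size=n_v)
    K = ranges.K_multiplier * H_star.max()
    return SampledRates(
        phi=np.tile(phi_v, (n_h, 1)),
        beta=np.tile(beta_v, (n_h, 1)),
        H_star=H_star,
        V_star=V_star,
        K=float(K),
    )


def derive_growth_and_decay(
    M: InfectionMatrix,
    phi: ArrayLike,
    beta: ArrayLike,
    H_star: ArrayLike,
    V_star: ArrayLike,
    K: float,
    a: ArrayLike = 1.0,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Solve the steady-state equations for (r, m) at targets (H*, V*).

    Returns strictly positive growth and decay rates; raises
    :class:`FeasibilityError` when the infection matrix or the carrying
    capacity make positive rates impossible.
    """
    shape = M.entries.shape
    phi = np.broadcast_to(np.asarray(phi, dtype=float), shape)
    beta = np.broadcast_to(np.asarray(beta, dtype=float), shape)
    H_star = np.asarray(H_star, dtype=float).ravel()
    V_star = np.asarray(V_star, dtype=float).ravel()
    a_mat = np.asarray(a, dtype=float)
    if a_mat.ndim == 0:
        a_mat = np.full((shape[0], shape[0]), float(a_mat))

    m = (M.entries * beta * phi).T @ H_star
    denom = 1.0 - a_mat @ H_star / K
    if (denom <= 0).any():
        raise FeasibilityError(
            "equilibrium host load exceeds carrying capacity; no positive growth rate exists"
        )
    r = (M.entries * phi) @ V_star / denom
    if (m <= 0).any() or (r <= 0).any():
        raise FeasibilityError(
            "derived rates are not strictly positive (empty row/column or zero rates)"
        )
    return r, m


def feasible_parameters(
    M: InfectionMatrix,
    ranges: ParameterRanges | None = None,
    seed: int | np.random.Generator | None = None,
    a: ArrayLike = 1.0,
) -> SystemParameters:
    """Draw free rates and solve for (r, m): a full feasible parameter set.

    The returned parameters make ``(H*, V*)`` an exact coexistence fixed
    point of the community dynamics for infection network ``M``.
    """
    ranges = ranges or ParameterRanges()
    drawn = sample_ranges(ranges, M.n_hosts, M.n_viruses, seed)
    a_mat = np.asarray(a, dtype=float)
    if a_mat.ndim == 0:
        a_mat = np.full((M.n_hosts, M.n_hosts), float(a_mat))
    r, m = derive_growth_and_decay(
        M, drawn.phi, drawn.beta, drawn.H_star, drawn.V_star, drawn.K, a_mat
    )
    return SystemParameters(
        r=r,
        a=a_mat,
        K=drawn.K,
        phi=drawn.phi,
        beta=drawn.beta,
        m=m,
        H_star=drawn.H_star,
        V_star=drawn.V_star,
    )
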