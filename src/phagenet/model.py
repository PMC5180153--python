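"""Multi-host, multi-virus Lotka-Volterra community model.

The community consists of ``N_h`` bacterial host types and ``N_v`` virus
(phage) types. Hosts grow logistically under a shared, competition-weighted
carrying capacity and are lysed by the viruses that infect them; viruses
replicate through lysis (burst size times adsorption rate) and decay at a
constant per-capita rate. Which virus infects which host is encoded by a
binary infection matrix ``M``; the element-wise product of ``M`` with the
adsorption rates and burst sizes is the *quantitative* infection network,
the object the reconstruction machinery estimates from time series.

All rates are per day; densities are per millilitre.

State-vector convention: the integrator works on a single concatenated
vector, hosts first then viruses, ``y = (h_1..h_Nh, v_1..v_Nv)``.
"""

from __future__ import annotations

import json
from dataclasses import InitVar, dataclass, field
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .exceptions import DimensionError, FeasibilityError

__all__ = [
    "InfectionMatrix",
    "QuantitativeNetwork",
    "SystemParameters",
    "CommunityState",
    "ode_rhs",
    "pack_state",
    "unpack_state",
]


def _as_2d(entries: ArrayLike, name: str) -> NDArray[np.float64]:
    arr = np.asarray(entries, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise DimensionError(f"{name} must be a non-empty 2-D matrix, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class InfectionMatrix:
    """Binary who-infects-whom matrix.

    Rows are host types, columns are virus types; entry (i, j) is 1 when
    virus j infects host i. Every host must have at least one infecting
    virus and every virus at least one host — matrices with empty rows or
    columns admit no positive coexistence equilibrium and are rejected.
    """

    entries: NDArray[np.int8]

    def __init__(self, entries: ArrayLike) -> None:
        arr = _as_2d(entries, "InfectionMatrix")
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("infection matrix entries must all be 0 or 1")
        if (arr.sum(axis=1) == 0).any():
            raise FeasibilityError("infection matrix has an all-zero row (host with no virus)")
        if (arr.sum(axis=0) == 0).any():
            raise FeasibilityError("infection matrix has an all-zero column (virus with no host)")
        object.__setattr__(self, "entries", arr.astype(np.int8))
        self.entries.setflags(write=False)

    @property
    def n_hosts(self) -> int:
        return self.entries.shape[0]

    @property
    def n_viruses(self) -> int:
        return self.entries.shape[1]

    @property
    def n_interactions(self) -> int:
        return int(self.entries.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InfectionMatrix):
            return NotImplemented
        return self.entries.shape == other.entries.shape and bool(
            (self.entries == other.entries).all()
        )


@dataclass(frozen=True)
class QuantitativeNetwork:
    """Non-negative matrix of effective infection rates.

    Entry (i, j) is ``M_ij * phi_ij * beta_ij`` — adsorption rate times burst
    size wherever the binary network has an interaction, zero elsewhere.
    Units: ml/(virus·day) × viruses/cell.
    """

    entries: NDArray[np.float64]

    def __init__(self, entries: ArrayLike) -> None:
        arr = _as_2d(entries, "QuantitativeNetwork")
        if (arr < 0).any():
            raise ValueError("quantitative network entries must be non-negative")
        object.__setattr__(self, "entries", arr)
        self.entries.setflags(write=False)

    @classmethod
    def from_components(
        cls, M: InfectionMatrix, phi: ArrayLike, beta: ArrayLike
    ) -> "QuantitativeNetwork":
        phi = np.broadcast_to(np.asarray(phi, dtype=float), M.entries.shape)
        beta = np.broadcast_to(np.asarray(beta, dtype=float), M.entries.shape)
        return cls(M.entries * phi * beta)

    @property
    def n_hosts(self) -> int:
        return self.entries.shape[0]

    @property
    def n_viruses(self) -> int:
        return self.entries.shape[1]

    def support(self, threshold_frac: float = 1e-2) -> NDArray[np.int8]:
        """Binary support after thresholding at ``threshold_frac * max entry``."""
        cut = threshold_frac * self.entries.max()
        return (self.entries > cut).astype(np.int8)

    def norm(self) -> float:
        """Frobenius norm of the rate matrix."""
        return float(np.linalg.norm(self.entries))


@dataclass
class CommunityState:
    """Host and virus density vectors (per ml).

    Densities must be non-negative; ``validate=False`` skips the check so the
    same container can carry time derivatives, which may be negative.
    """

    h: NDArray[np.float64]
    v: NDArray[np.float64]
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.h = np.asarray(self.h, dtype=float).ravel()
        self.v = np.asarray(self.v, dtype=float).ravel()
        if validate and ((self.h < 0).any() or (self.v < 0).any()):
            raise ValueError("densities must be non-negative")


def pack_state(state: CommunityState) -> NDArray[np.float64]:
    """Concatenate a community state into one vector, hosts first."""
    return np.concatenate([state.h, state.v])


def unpack_state(y: ArrayLike, n_hosts: int) -> CommunityState:
    """Inverse of :func:`pack_state`."""
    y = np.asarray(y, dtype=float).ravel()
    return CommunityState(h=y[:n_hosts], v=y[n_hosts:])


@dataclass
class SystemParameters:
    """All rate constants of the community model plus its target equilibrium.

    Attributes
    ----------
    r : (N_h,) host growth rates in the absence of viruses, 1/day.
    a : (N_h, N_h) dimensionless competition coefficients; ``a[i, ip]`` is
        the competitive effect of host ``ip`` on host ``i``. The default
        used throughout the package is all ones (a single shared carrying
        capacity).
    K : scalar system-wide carrying capacity, cells/ml.
    phi : (N_h, N_v) adsorption rates, ml/(virus·day).
    beta : (N_h, N_v) burst sizes, viruses/cell.
    m : (N_v,) viral decay rates, 1/day.
    H_star, V_star : target coexistence equilibrium densities, per ml.
    """

    r: NDArray[np.float64]
    a: NDArray[np.float64]
    K: float
    phi: NDArray[np.float64]
    beta: NDArray[np.float64]
    m: NDArray[np.float64]
    H_star: NDArray[np.float64]
    V_star: NDArray[np.float64]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float).ravel()
        self.m = np.asarray(self.m, dtype=float).ravel()
        self.H_star = np.asarray(self.H_star, dtype=float).ravel()
        self.V_star = np.asarray(self.V_star, dtype=float).ravel()
        n_h, n_v = self.r.size, self.m.size
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim == 0:
            self.a = np.full((n_h, n_h), float(self.a))
        self.phi = np.broadcast_to(np.asarray(self.phi, dtype=float), (n_h, n_v)).copy()
        self.beta = np.broadcast_to(np.asarray(self.beta, dtype=float), (n_h, n_v)).copy()
        self.K = float(self.K)

        if self.a.shape != (n_h, n_h):
            raise DimensionError(f"competition matrix must be {(n_h, n_h)}, got {self.a.shape}")
        if self.H_star.size != n_h or self.V_star.size != n_v:
            raise DimensionError("equilibrium target sizes do not match r / m")
        if (self.r <= 0).any() or (self.m <= 0).any() or self.K <= 0:
            raise ValueError("r, m and K must be strictly positive")
        if (self.phi < 0).any() or (self.beta < 0).any():
            raise ValueError("phi and beta must be non-negative")
        if (self.H_star < 0).any() or (self.V_star < 0).any():
            raise ValueError("equilibrium targets must be non-negative")
        denom = 1.0 - self.a @ self.H_star / self.K
        if (denom <= 0).any():
            raise FeasibilityError(
                "competition-weighted equilibrium load exceeds the carrying capacity "
                "(1 - sum_i' a_ii' H*_i' / K must stay positive)"
            )

    @property
    def n_hosts(self) -> int:
        return self.r.size

    @property
    def n_viruses(self) -> int:
        return self.m.size

    def quantitative_network(self, M: InfectionMatrix) -> QuantitativeNetwork:
        """Effective infection-rate matrix ``M ∘ phi ∘ beta`` for network ``M``."""
        return QuantitativeNetwork.from_components(M, self.phi, self.beta)

    def equilibrium(self) -> CommunityState:
        return CommunityState(h=self.H_star.copy(), v=self.V_star.copy())

    # -- JSON round trip ---------------------------------------------------

    _UNITS = {
        "r": "1/day",
        "a": "dimensionless",
        "K": "cells/ml",
        "phi": "ml/(virus*day)",
        "beta": "viruses/cell",
        "m": "1/day",
        "H_star": "cells/ml",
        "V_star": "viruses/ml",
    }

    def to_dict(self) -> dict[str, Any]:
        return {
            "r": self.r.tolist(),
            "a": self.a.tolist(),
            "K": self.K,
            "phi": self.phi.tolist(),
            "beta": self.beta.tolist(),
            "m": self.m.tolist(),
            "H_star": self.H_star.tolist(),
            "V_star": self.V_star.tolist(),
            "units": dict(self._UNITS),
            "meta": self.meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "SystemParameters":
        keys = ("r", "a", "K", "phi", "beta", "m", "H_star", "V_star")
        return cls(**{k: doc[k] for k in keys}, meta=doc.get("meta", {}))

    @classmethod
    def from_json(cls, path) -> "SystemParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def ode_rhs(
    state: CommunityState, params: SystemParameters, M: InfectionMatrix
) -> CommunityState:
    """Time derivative (per day) of the community state.

    Host ``i``:   ``dh_i/dt = r_i h_i (1 - Σ_i' a_ii' h_i'/K) - h_i Σ_j M_ij φ_ij v_j``
    Virus ``j``:  ``dv_j/dt = v_j Σ_i β_ij φ_ij M_ij h_i - m_j v_j``

    Every term carries the focal density as a factor, so the field never
    drives a zero component negative.
    """
    h, v = state.h, state.v
    if h.size != params.n_hosts or v.size != params.n_viruses:
        raise DimensionError(
            f"state has {h.size} hosts / {v.size} viruses, parameters expect "
            f"{params.n_hosts} / {params.n_viruses}"
        )
    if M.entries.shape != (params.n_hosts, params.n_viruses):
        raise DimensionError(
            f"infection matrix shape {M.entries.shape} does not match parameters"
        )
    mphi = M.entries * params.phi
    dh = params.r * h * (1.0 - params.a @ h / params.K) - h * (mphi @ v)
    dv = v * ((mphi * params.beta).T @ h) - params.m * v
    return CommunityState(dh, dv, validate=False)
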