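"""Nestedness (NODF) and ensembles of binary infection matrices.

A bipartite infection network is *nested* when host ranges and phage ranges
form ordered subsets: the viruses infecting a narrow-range host are a subset
of those infecting a broad-range host, and vice versa. NODF (nestedness by
overlap and decreasing fill) quantifies this on a 0-1 scale.

Convention used here: for every unordered pair of rows (and of columns), a
pair whose degrees are *equal* contributes 0 — the strict decreasing-fill
rule — while a pair with unequal degrees contributes the fraction of the
sparser line's interactions that are overlapped by the denser line. NODF is
the mean contribution over all row pairs and column pairs, so it is
normalised to [0, 1] and invariant under row/column permutations.

The ensemble generator starts from a block-diagonal (modular) matrix and
hill-climbs by relocating single interactions, accepting moves that do not
decrease NODF; snapshots along the climb give a spectrum of matrices with
identical shape and fill but increasing nestedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import NDArray

from .exceptions import DimensionError
from .model import InfectionMatrix

__all__ = [
    "nodf",
    "max_nested_matrix",
    "modular_matrix",
    "random_matrix",
    "nestedness_ensemble",
    "MatrixEnsemble",
]


def _nodf_array(A: NDArray[np.float64]) -> float:
    n_r, n_c = A.shape
    total_pairs = n_r * (n_r - 1) // 2 + n_c * (n_c - 1) // 2
    if total_pairs == 0:
        return 0.0
    score = 0.0
    for B in (A, A.T):
        k = B.sum(axis=1)
        overlap = B @ B.T
        kmin = np.minimum.outer(k, k)
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(
                np.not_equal.outer(k, k) & (kmin > 0), overlap / kmin, 0.0
            )
        iu = np.triu_indices(B.shape[0], k=1)
        score += contrib[iu].sum()
    return float(score / total_pairs)


def nodf(M: InfectionMatrix | NDArray) -> float:
    """NODF nestedness of a binary matrix, normalised to [0, 1].

    Raises
    ------
    ValueError
        If the matrix is all-zero (NODF is undefined).
    """
    A = M.entries if isinstance(M, InfectionMatrix) else np.asarray(M)
    A = A.astype(float)
    if A.ndim != 2 or A.size == 0:
        raise DimensionError("nodf requires a non-empty 2-D matrix")
    if not A.any():
        raise ValueError("NODF is undefined for an all-zero matrix")
    return _nodf_array(A)


def _prefix_matrix(lengths: Sequence[int], n_v: int) -> NDArray[np.int8]:
    """Upper-left-justified matrix whose row i holds a prefix of `lengths[i]` ones."""
    out = np.zeros((len(lengths), n_v), dtype=np.int8)
    for i, L in enumerate(lengths):
        out[i, :L] = 1
    return out


def max_nested_matrix(n_h: int, n_v: int, n_interactions: int) -> InfectionMatrix:
    """Upper-left-justified staircase matrix maximising NODF at the given fill.

    When the fill admits strictly decreasing row and column degrees (for a
    square matrix with no empty lines this forces ``n = n_h(n_h+1)/2``) the
    result scores NODF = 1; otherwise degree ties are unavoidable and the
    construction returns the best staircase found by greedy growth plus a
    deterministic local search.
    """
    if n_h < 1 or n_v < 1:
        raise DimensionError("matrix dimensions must be positive")
    if n_interactions < max(n_h, n_v) or n_interactions > n_h * n_v:
        raise ValueError(
            f"fill {n_interactions} infeasible for a {n_h}x{n_v} matrix with no "
            "empty rows or columns"
        )

    if n_interactions >= n_h + n_v - 1:
        # prefix (staircase) construction: row 0 spans all columns so every
        # column is covered; grow the remaining rows greedily on NODF
        lengths = [n_v] + [1] * (n_h - 1)
        remaining = n_interactions - sum(lengths)
        current = _nodf_array(_prefix_matrix(lengths, n_v).astype(float))
        for _ in range(remaining):
            best_i, best_val = -1, -1.0
            for i in range(1, n_h):
                cap = lengths[i - 1] if i > 0 else n_v
                if lengths[i] >= min(cap, n_v):
                    continue
                lengths[i] += 1
                val = _nodf_array(_prefix_matrix(lengths, n_v).astype(float))
                lengths[i] -= 1
                if val > best_val:
                    best_i, best_val = i, val
            lengths[best_i] += 1
            current = best_val
        A = _prefix_matrix(lengths, n_v)
    else:
        # too sparse for a full-width top row: diagonal band start
        A = np.zeros((n_h, n_v), dtype=np.int8)
        for i in range(n_h):
            A[i, min(i, n_v - 1)] = 1
        for j in range(n_v):
            if A[:, j].sum() == 0:
                A[min(j, n_h - 1), j] = 1
        extra = n_interactions - int(A.sum())
        flat_empty = np.flatnonzero(A.ravel() == 0)
        A.ravel()[flat_empty[:extra]] = 1

    A = _polish(A, max_iter=20_000, rng=np.random.default_rng(0))
    return InfectionMatrix(A)


def _polish(A: NDArray[np.int8], max_iter: int, rng: np.random.Generator) -> NDArray[np.int8]:
    """Local search: relocate single interactions while NODF does not decrease.

    Sideways (NODF-preserving) moves are accepted so plateaus can be crossed;
    the best matrix seen is returned.
    """
    A = A.astype(np.int8).copy()
    current = _nodf_array(A.astype(float))
    best, best_val = A.copy(), current
    stall = 0
    for _ in range(max_iter):
        if best_val >= 1.0 - 1e-12 or stall > 3000:
            break
        accepted = _try_move(A, current, rng, strict=False)
        if accepted is None:
            stall += 1
        else:
            if accepted > best_val + 1e-15:
                best, best_val = A.copy(), accepted
                stall = 0
            else:
                stall += 1
            current = accepted
    return best


def _try_move(
    A: NDArray[np.int8], current: float, rng: np.random.Generator, strict: bool
) -> float | None:
    """Move one interaction to an empty cell in place; revert on rejection.

    Returns the new NODF on acceptance, ``None`` on rejection. A move is
    rejected when it would empty a row/column or when NODF decreases
    (``strict=True`` additionally rejects NODF-preserving moves).
    """
    filled = np.argwhere(A == 1)
    empty = np.argwhere(A == 0)
    if len(empty) == 0:
        return None
    i, j = filled[rng.integers(len(filled))]
    k, l = empty[rng.integers(len(empty))]
    if (A[i, :].sum() == 1 and k != i) or (A[:, j].sum() == 1 and l != j):
        return None
    A[i, j], A[k, l] = 0, 1
    val = _nodf_array(A.astype(float))
    ok = val > current + 1e-15 if strict else val >= current - 1e-15
    if ok:
        return val
    A[i, j], A[k, l] = 1, 0
    return None


def modular_matrix(
    n_h: int, n_v: int, n_modules: int, seed: int | None = None
) -> InfectionMatrix:
    """Block-diagonal matrix of fully connected host-virus modules.

    Rows and columns are partitioned as evenly as possible into
    ``n_modules`` groups and each group forms an all-ones block. The
    construction is deterministic; ``seed`` is accepted for interface
    uniformity with the other generators and is unused.
    """
    if n_modules < 1 or n_modules > min(n_h, n_v):
        raise ValueError("n_modules must be between 1 and min(n_h, n_v)")
    A = np.zeros((n_h, n_v), dtype=np.int8)
    row_groups = np.array_split(np.arange(n_h), n_modules)
    col_groups = np.array_split(np.arange(n_v), n_modules)
    for rows, cols in zip(row_groups, col_groups):
        A[np.ix_(rows, cols)] = 1
    return InfectionMatrix(A)


def random_matrix(
    n_h: int,
    n_v: int,
    n_interactions: int,
    seed: int | np.random.Generator | None = None,
    distinct_rows: bool = False,
    max_tries: int = 1000,
) -> InfectionMatrix:
    """Uniform random binary matrix with a fixed fill and no empty lines.

    One interaction is first placed per row and per column (via a random
    assignment), then the remaining fill is scattered uniformly over empty
    cells. With ``distinct_rows=True`` the draw is rejected until all host
    ranges differ — hosts with identical virus sets (and shared per-virus
    adsorption rates) have exactly proportional trajectories, which makes
    their rates unidentifiable from a single experiment.
    """
    if n_interactions < max(n_h, n_v) or n_interactions > n_h * n_v:
        raise ValueError("infeasible fill for a matrix with no empty rows/columns")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        A = np.zeros((n_h, n_v), dtype=np.int8)
        cols = rng.permutation(n_v)
        for i in range(n_h):
            A[i, cols[i % n_v]] = 1
        for j in range(n_v):
            if A[:, j].sum() == 0:
                A[rng.integers(n_h), j] = 1
        extra = n_interactions - int(A.sum())
        if extra < 0:
            continue
        empty = np.flatnonzero(A.ravel() == 0)
        A.ravel()[rng.choice(empty, size=extra, replace=False)] = 1
        if distinct_rows and len({r.tobytes() for r in A}) < n_h:
            continue
        return InfectionMatrix(A)
    raise RuntimeError("could not draw a matrix satisfying the constraints")


@dataclass
class MatrixEnsemble:
    """Ordered collection of same-shape, same-fill infection matrices.

    ``nodf_values[k]`` is the NODF of ``matrices[k]``; the generator emits
    them in non-decreasing order. ``complete`` is False when the hill climb
    exhausted its iteration budget before producing the requested number of
    distinct snapshots.
    """

    matrices: list[InfectionMatrix]
    nodf_values: NDArray[np.float64]
    complete: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodf_values = np.asarray(self.nodf_values, dtype=float)
        if len(self.matrices) != self.nodf_values.size:
            raise DimensionError("one NODF value per matrix required")
        shapes = {m.entries.shape for m in self.matrices}
        fills = {m.n_interactions for m in self.matrices}
        if len(shapes) > 1 or len(fills) > 1:
            raise ValueError("ensemble matrices must share shape and fill")

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)


def nestedness_ensemble(
    n_h: int = 10,
    n_v: int = 10,
    n_modules: int = 5,
    n_matrices: int = 100,
    seed: int | None = None,
    max_iter: int = 40_000,
) -> MatrixEnsemble:
    """Generate matrices spanning a spectrum of nestedness at fixed fill.

    Starting from :func:`modular_matrix`, single interactions are moved to
    empty cells, accepting any move that does not decrease NODF and never
    emptying a row or column; the number of interactions is conserved.
    Snapshots are recorded whenever NODF improves, and ``n_matrices`` of them
    are selected on an (approximately) even NODF grid between the modular
    start and the most-nested state reached.
    """
    if n_matrices < 2:
        raise ValueError("n_matrices must be at least 2")
    rng = np.random.default_rng(seed)
    A = modular_matrix(n_h, n_v, n_modules).entries.astype(np.int8).copy()
    current = _nodf_array(A.astype(float))
    trajectory: list[tuple[float, NDArray[np.int8]]] = [(current, A.copy())]

    stall = 0
    for _ in range(max_iter):
        if current >= 1.0 - 1e-12 or stall > 3000:
            break
        new = _try_move(A, current, rng, strict=False)
        if new is None:
            stall += 1
            continue
        # sideways moves are recorded too: they change the matrix (more
        # distinct snapshots) without lowering NODF, and un-stick plateaus
        stall = 0 if new > current + 1e-15 else stall + 1
        current = new
        trajectory.append((current, A.copy()))

    # pick snapshots on an even NODF grid, greedily forced distinct
    values = np.array([v for v, _ in trajectory])
    targets = np.linspace(values[0], values[-1], n_matrices)
    picks: list[int] = []
    prev = -1
    for t in targets:
        p = int(np.searchsorted(values, t, side="left"))
        p = min(max(p, prev + 1), len(values) - 1)
        picks.append(p)
        prev = p
    complete = len(set(picks)) == n_matrices
    matrices = [InfectionMatrix(trajectory[p][1]) for p in picks]
    return MatrixEnsemble(
        matrices=matrices,
        nodf_values=values[picks],
        complete=complete,
        meta={
            "n_h": n_h,
            "n_v": n_v,
            "n_modules": n_modules,
            "seed": seed,
            "fill": int(matrices[0].n_interactions),
            "n_snapshots_available": len(trajectory),
        },
    )
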