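# Methods

## The community model

`phagenet` models `N_h` bacterial host types and `N_v` lytic virus (phage)
types with generalized Lotka–Volterra dynamics. Hosts grow logistically
against a single, competition-weighted carrying capacity and die by lysis;
viruses are produced by lysis (burst size × adsorption rate) and decay at a
constant per-capita rate:

    dh_i/dt = r_i h_i (1 − Σ_i' a_ii' h_i'/K) − h_i Σ_j M_ij φ_ij v_j
    dv_j/dt = v_j Σ_i β_ij φ_ij M_ij h_i − m_j v_j

All rates are per day, densities per millilitre. The binary matrix `M`
(rows hosts, columns viruses) states who infects whom; the element-wise
product `M̃ = M ∘ φ ∘ β` of the infection matrix with adsorption rates and
burst sizes is the quantitative infection network that the inference
recovers. Model assumptions worth keeping in mind: mass-action adsorption
with immediate lysis (no latent period, no lysogeny or persistent
infection), no intrinsic virus growth, no host refuges, and no evolution of
host range on the measurement timescale.

The integrator state is one concatenated vector, hosts first, viruses
second; this ordering is fixed everywhere.

### Default parameters

| parameter | default | units | origin |
|---|---|---|---|
| φ_j (adsorption) | U(1e-8, 1e-7), per virus | ml/(virus·d) | feasibility table |
| β_j (burst size) | U(10, 50), per virus | viruses/cell | feasibility table |
| H*_i (host equilibrium) | U(1e3, 1e4) | cells/ml | feasibility table |
| V*_j (virus equilibrium) | U(1e6, 1e7) | virus/ml | feasibility table |
| K (carrying capacity) | 100 × max_i H*_i (= 1e6 at the range top) | cells/ml | feasibility table |
| a_ii' (competition) | 1 for all pairs | — | package default (see below) |
| δ (initial displacement) | 0.5 | — | package default (see below) |
| Δt (sampling interval) | 6 | min | reference design |
| T (horizon) | 96 | h | reference design |

φ and β are drawn once per *virus* and broadcast across hosts; per-pair
matrices are accepted everywhere for generality. The competition matrix is
not pinned down by the source material; all-ones (a pure shared carrying
capacity, exactly the form of the host equation above) is the natural
reading, and with the table ranges it keeps the feasibility denominator
`1 − Σ a H*/K ≥ 0.9`. K is carried as cells/ml; the listed "(ml)" unit is
treated as a typographical artifact.

## Feasibility-based parameter generation

Rather than rejection-sampling for coexistence, the generator solves the
steady-state equations for the remaining rates. With targets `(H*, V*)`
drawn from the ranges above,

    m_j = Σ_i M_ij β_ij φ_ij H*_i
    r_i = (Σ_j M_ij φ_ij V*_j) / (1 − Σ_i' a_ii' H*_i'/K),

so `(H*, V*)` is an exact interior fixed point by construction (verified to
1e-10 relative residual in the tests). Both rates are strictly positive iff
every host has a virus and every virus a host — hence the no-empty-line
invariant on infection matrices. No stability screening is applied: the
derived systems are used as-is, and the engineered equilibria are typically
neutrally-to-weakly stable with slow dynamics (see "Implications" below).

## Nestedness ensembles

NODF is computed with the strict decreasing-fill convention: for each
unordered pair of rows (and of columns), equal degrees contribute 0;
unequal degrees contribute the fraction of the sparser line's interactions
overlapped by the denser line. The mean over all pairs is normalised to
[0, 1] and is invariant under row/column permutation. Consequence: a 10×10
matrix with no empty rows scores exactly 1 only when its row degrees are
ten distinct values, i.e. at exactly 55 interactions (the full staircase).
At any other fill the maximum is below 1; `max_nested_matrix` constructs
the best staircase it can (greedy prefix growth plus deterministic local
search, verified exhaustively on small shapes).

Ensembles start from a block-diagonal modular matrix (default 5 modules,
hence 20 interactions at 10×10) and relocate one interaction at a time,
accepting moves that do not decrease NODF and never emptying a row or
column; fill is conserved. Snapshots are taken along the climb on an
approximately even NODF grid. Because NODF improvements come in discrete
jumps, NODF-preserving (sideways) accepted moves are also recorded so that
the requested number of distinct matrices is available; the `complete` flag
reports whether it was.

## Simulation and measurement emulation

Initial conditions displace every population independently to
`x_eq(1 ± δ)` with a fair coin per population. δ = 0.5 is the package
default for all headline analyses; the source material does not state the
value it used, and absolute error levels depend on it (error decreases as δ
grows — a δ sweep is part of the evaluation suite).

Integration uses the Dormand–Prince RK45 pair (`scipy.integrate.solve_ivp`)
with `rtol = 1e-8` and a per-type absolute tolerance of `1e-8 × x_eq`
(hosts and viruses live three orders of magnitude apart, so one absolute
tolerance cannot serve both). The sample grid `t = 0, Δt, …, T` comes from
the solver's dense output and is exact to 1e-9 relative regardless of the
internal steps. "Measurements" are counted as sampling intervals — the
number of usable regression columns — so the 6-min/96-h design counts 960
(from 961 grid points).

Measurement noise is additive white Gaussian, scaled per trajectory:
`σ² = mean(x²) / 10^(SNR_dB/10)`, applied to hosts and viruses alike by
default (a viruses-only flag exists for sensitivity analysis). Noisy values
at or below zero are clipped to `1e-6 × min(series)` so logarithms stay
finite; the floor is configurable and recorded in the series metadata.
Noise is added to densities before the log transform.

## Reconstruction

`build_regression` forms `W` from forward log-differences and pairs column
`n` with the host densities at the left interval endpoint `t_n`, the
convention implied by the discretized virus equation. The exact identity is
`Δln v_j/Δt = Σ_i M̃_ij h̄_i − m_j` with `h̄` the *interval average* of the
hosts, so the left endpoint commits an O(Δt) error and the optional
midpoint variant (`midpoint=True`, endpoint average) an O(Δt²) one. The
forward convention is the default; the midpoint flag exists for accuracy
experiments and is excluded from the evaluation runs.

The constrained problem separates across virus rows into non-negative
least-squares problems of dimension `N_h + 1` (the decay rate enters
through a negated ones-column). The default solver is Lawson–Hanson
active-set NNLS (`scipy.optimize.nnls`); `lsq_linear` (bounded
trust-region) is available as an independent cross-check and the two agree
to 1e-8 in objective on well-posed systems. The strict positivity `m > 0`
is relaxed to `m ≥ 0` (a closed feasible set; strict inequalities have no
attained minimizer in general) and positivity of recovered decay rates is
reported rather than enforced. No regularization is applied anywhere in the
evaluation; a ridge option exists behind a flag (default 0) for noisy-data
exploration only.

Diagnostics: the condition number of `(H; 1)` is always computed and a
`ConditioningWarning` is raised above 1e10 or when the system is
underdetermined; `summary()` reports it next to the objective, since
near-equilibrium data (δ → 0) fails exactly this way.

## Evaluation sweeps

Each sweep is a pure function of (matrices, design, master seed): every
(matrix, grid point, replicate) triple draws its generator from
`SeedSequence(master, spawn_key=(role, …indices))`, making grid points
independent yet bit-reproducible. Failures in individual runs are recorded
as NaN with a reason in `meta['failures']` and never abort a sweep.
Mean and standard deviation columns are NaN-aware aggregates of the stored
per-matrix error table and can always be re-derived from it.

The multi-experiment sweep simulates, per matrix, a pool of `max(p)` runs
at the full 960-column horizon and slices the first `960//p` regression
columns per run. This is equivalent to simulating per (p, run) — the first
columns of a trajectory do not depend on the horizon — and it makes the
p = 1 case identical to the single-experiment pipeline by construction.
When p does not divide the budget the remainder is truncated and the
realised budget recorded.

Ensemble-scale defaults: evaluation protocols run on 20-matrix ensembles;
the SNR sweep uses the 20-experiment × 48-column design.

## Implications of the engineered equilibria (what the tests do and do not show)

The feasibility construction with the table ranges yields slow viral
dynamics: `m = βφH*` lands at 0.01–0.05 per day, giving community
oscillation periods of 50–90 days. Over a 96-hour window, host trajectories
are therefore smooth, low-curvature arcs, and the single-experiment
regression is severely ill-conditioned even at δ = 0.5 — the data, not the
solver, are the limit. Quantitatively, with exact (analytic)
log-derivatives the solver recovers the generating network to ~1e-7
relative even on these windows; with finite-difference `W`, typical
single-experiment errors are 0.05–0.5, falling to ~0.01 only for favorably
conditioned draws (roughly one seed in twenty), to ~0.007 when the horizon
is extended to 40 days, and to ~0.002 with the pooled 20 × 48 design at the
same 960-column budget. The evaluation suite therefore gates *trends* — the
δ dependence, the single-vs-multi ordering and optimal split, the interior
optimum of the fixed-budget sampling-interval slice, monotone degradation
with SNR — rather than absolute single-experiment error levels.

Two structural facts discovered by the analysis are worth recording. First,
hosts with identical infection-matrix rows are exactly unidentifiable from
one experiment when φ is per-virus and competition is uniform: their
log-density derivatives coincide, so their trajectories stay exactly
proportional and only the sum of their rates is determined. The
single-system showcase generator therefore conditions on distinct host
rows (`random_matrix(distinct_rows=True)`); multi-experiment pooling
resolves the ambiguity naturally because the proportionality constant
differs per experiment. Second, on near-degenerate single-experiment
designs the constrained optimum occasionally runs far along a nearly flat
direction (errors ≫ 1); this is the true optimum, not a solver artifact (a
minimum-norm tie-break among near-optimal solutions was tested and does not
move it), so ensemble means at small δ are outlier-dominated and the
per-matrix median is the stable summary of the typical case.

## What the synthetic data do not emulate

Demographic stochasticity, multiplicative (lognormal) measurement error,
irregular sampling grids, within-experiment evolution of host range,
latent-period delays, lysogeny, and strain-calling error from sequencing
pipelines. Passing tests demonstrate correctness of the inference machinery
under the stated model, not robustness to model misspecification.

## Numerical choices, briefly

- NNLS per row; KKT-clean active-set solutions; condition number logged.
- RK45, rtol 1e-8, per-type atol; dense-output sampling.
- Ties in the nestedness local search broken by the seeded generator;
  matrix constructions deterministic given the seed.
- Noise clipping floor 1e-6 × series minimum (keeps logs finite without
  biasing high-SNR regimes).
- All file writers emit 17-significant-digit floats; CSV reads use the
  round-trip float parser so write/read is bit-exact.
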