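# phagenet

Inference of quantitative phage–bacteria infection networks from community
time-series data.

In a microbial community, each phage type infects only a subset of the
bacterial host types. The classical way to establish this *infection
network* — the plaque assay — tests one phage–host pair at a time and does
not scale to diverse, largely uncultured environmental communities.
`phagenet` implements a community-scale alternative: given densities of all
host and virus types sampled over time, it reconstructs the full network of
effective infection rates by regression on the virus equations of a
generalized Lotka–Volterra model, without testing any pair individually.

## Model and method

Hosts `h_i` (i = 1..N_h) and free viruses `v_j` (j = 1..N_v) follow

    dh_i/dt = r_i h_i (1 − Σ_i' a_ii' h_i'/K) − h_i Σ_j M_ij φ_ij v_j
    dv_j/dt = v_j Σ_i β_ij φ_ij M_ij h_i − m_j v_j

with growth rates `r_i`, shared carrying capacity `K`, adsorption rates
`φ_ij`, burst sizes `β_ij`, viral decay rates `m_j` and the binary infection
matrix `M`. The virus equations are linear in the hosts once written for
`ln v_j`:

    d ln(v_j)/dt = Σ_i M̃_ij h_i − m_j,     M̃_ij := M_ij φ_ij β_ij,

where `M̃` is the **quantitative infection network**, the object of
inference. From `N+1` measurements, finite differences
`Δln v_j(t_n)/Δt_n` form a matrix `W` (one column per sampling interval),
host densities form `H`, and `(M̃, m)` solve the constrained least-squares
problem

    argmin ‖W − (M̃ᵀ −m)(H; 1)‖_F   subject to  M̃ ≥ 0, m ≥ 0,

which separates into one non-negative least-squares problem per virus.
Reconstruction quality against a known network is the normalized Frobenius
error `‖M̃ − M̃_rec‖_F / ‖M̃‖_F`. Columns from multiple experiments that
differ only in initial conditions can be pooled, which conditions the
regression far better than one long experiment at the same measurement
budget.

The package also provides everything needed for in silico evaluation:
ensembles of binary matrices spanning a spectrum of nestedness (NODF),
feasibility-based parameter generation (growth and decay rates solved from
the steady-state equations so a positive equilibrium exists by
construction), an ODE simulator with δ-perturbed initial conditions and
Gaussian measurement noise at prescribed SNR, and experiment-design sweeps
(δ, number of experiments, sampling interval × horizon, SNR).

## Worked example

```python
import numpy as np
import phagenet as pn

# a 10-host / 10-virus community with 20 interactions
M = pn.random_matrix(10, 10, 20, seed=0, distinct_rows=True)
params = pn.feasible_parameters(M, seed=1)     # (H*, V*) is a fixed point
truth = params.quantitative_network(M)

# twenty short experiments: 4.8 h each, sampled every 6 min
series = []
for k in range(20):
    init = pn.perturbed_initial_state(params.H_star, params.V_star, 0.5, seed=k)
    series.append(pn.integrate_and_sample(params, M, init, dt=6/1440, T=4.8/24))

res = pn.NetworkReconstruction(series).fit()
print(f"Error_rec = {res.error(truth):.4f}")
print(f"interactions recovered: {int((res.support() == M.entries).all())}")
print(res.summary())
```

Output:

```
Error_rec = 0.0015
interactions recovered: 1
Quantitative infection network reconstruction
======================================================
hosts: 10   viruses: 10   regression columns: 960
solver: nnls   converged: True
objective (Frobenius residual): 2.185101e-03
cond(H_aug): 2.219e+05
inferred interactions (support at 1% of max): 20
decay rates m_rec [1/day]: min 0.002639, max 0.06814
```

The pooled 20×48-column reconstruction recovers all 20 interactions with a
0.15 % rate error; the same budget spent on one 96-hour experiment typically
does an order of magnitude worse because a single trajectory explores too
little of host-density space.

A command-line interface mirrors the pipeline
(`phagenet ensemble|params|simulate|reconstruct|sweep`, see `--help`).

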