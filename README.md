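# cyclehop

Encode periodic time-series gene expression as a cyclic sequence of Boolean
attractors in a Hopfield network, simulate noisy populations of model cells,
and search for small sets of gene inhibitions that arrest the cycle.

The package is aimed at computational biologists studying oscillatory
programs such as the cell cycle from bulk time-course transcriptomics. It
turns a gene × time expression matrix into a dynamical model whose
perturbations (e.g. kinase inhibition) can be screened *in silico*.

## The model

**Encoding.** Each gene's trajectory is fit to a decaying sinusoid

    x_i(t) = a_i e^(-b_i t) cos(omega_i t - phi_i) + x_i0

by bounded nonlinear least squares. A gene is called periodic when its
maximum relative parameter uncertainty

    r_i_max = max(dx_i0/x_i0, da_i/a_i, db_i/b_i, domega_i/omega_i, dphi_i/2pi)

falls below a threshold (default 0.3). Kept genes are refit with the
frequency fixed at the population mean, the fitted curves are discretized to
xi_i(t) = sign(x_i(t) - x_i0) in {-1, +1}, and one period is sampled at
p = 8 uniformly spaced times, giving attractor patterns xi^0 ... xi^7. Because
each gene is over-expressed for exactly half the cycle, xi^(mu+4) = -xi^mu.

**Dynamics.** N spins sigma_i(t) = ±1 evolve under the local field
h_i = sum_j J_ij sigma_j + h_i_ext with the stochastic rule
P(sigma_i(t+1) = +1) = (1 + e^(-2 h_i/T))^-1 at effective temperature T,
updated asynchronously (each node with probability 0.2 per step). The
coupling matrix blends the pseudo-inverse point rule J' (each pattern a
fixed point, J' xi^mu = xi^mu / p) with its cyclic counterpart J~
(J~ xi^mu = xi^(mu+1) / p):

    J(lambda) = (1 - lambda) J' + lambda J~ ,

then entries below the median |J_ij| are zeroed. At intermediate lambda and
T the system dwells in each state and hops forward under noise — a delayed
cyclic attractor. Populations of kappa independent cells are summarized by
the per-cell overlaps m_k^mu, states s_k = argmax_mu m_k^mu, and occupancies
P_mu(t), with time average <P_mu>_T.

**Control.** Inhibiting gene i is the h_i_ext -> -infinity limit, realized
as a clamp to -1. A target set is scored by <P_mu>_T during inhibition; a
genetic algorithm searches fixed-size target sets for the score maximizer,
with brute-force enumeration available on small pools as an independent
check.

## Worked example

Generate a synthetic time course (60 periodic + 40 noise genes), encode it,
simulate a population, and screen inhibition pairs:

```
$ cyclehop synth --out-dir data --n-periodic 60 --n-noise 40 --seed 5
wrote 100 genes x 40 times to data

$ cyclehop encode data/expression.csv --out-dir enc
60/100 genes periodic; 8 attractors -> enc

$ cyclehop simulate enc/attractors.tsv --out-dir sim --kappa 200 --steps 800
simulated 200 cells for 800 steps -> sim

$ cyclehop search enc/attractors.tsv --out-dir srch --objective-mu 7 \
      --n-targ 2 --exhaustive --seed 3
best set: G0043;G0046 (score 0.266) -> srch
```

`encode` recovered exactly the 60 planted periodic genes and wrote their
fits (`fits.tsv`) and the 8 × 60 attractor table (`attractors.tsv`).
`simulate` writes the occupancy time course `occupancy.tsv`; its first rows
show all eight P_mu near 1/8 = 0.125, the desynchronized steady state:

```
t       P_0      P_1      P_2      P_3      P_4      P_5      P_6      P_7
0       0.160000 0.150000 0.130000 0.155000 0.105000 0.090000 0.135000 0.075000
```

`search` ranks all 1770 candidate pairs; the winner holds 26.6% of cells in
state 7 during inhibition, versus 12.5% with no control — a two-gene
inhibition that visibly stalls the cycle. Every command writes a manifest
JSON capturing the configuration and seeds needed to reproduce its outputs
byte-for-byte.

The same `encode` command accepts real CSV/TSV/XLSX matrices whose header
row holds sampling times in minutes and whose first column holds gene
identifiers.

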