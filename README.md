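# rnaorder

Order/complexity metrics for mixtures of monomers and oligomer chains,
aimed at rating the progress of prebiotic molecular evolution.

The package provides:

- **Sequential entropy** (`rnaorder.entropy`): a closed-form entropy
  `S_r` for the ensemble of nearest-neighbour walks through a mixture,
  decomposed into monomer-mixing, chain-contact and sequence terms; its
  reciprocal `1/S_r` (K/J) is the system's *order*. The four limiting
  cases (pure monomer, crystals, random chains, defined chains) are
  exposed as closed forms.
- **Description-length complexity** (`rnaorder.complexity`): the
  smaller of two concrete encodings — a permutation census (`c1`) and
  an explicit sequence listing (`c2`) — with overflow-safe log-scale
  evaluation for mole-sized systems.
- **Parameter sweeps** (`rnaorder.sweeps`): order-vs-complexity
  trajectories along the random-chain fraction `p`, the mean chain
  length `L` and the monomer spacing `M`, written as CSV/JSON and
  optionally plotted.
- **Evolution simulator** (`rnaorder.evolution`): a deterministic
  mutation/selection scheme — constant selection rate `dp/dt`
  punctuated by periodic mutation events that lengthen the defined
  sequence while converting a fraction of defined chains back to
  random.
- **Microstate oracle** (`rnaorder.oracle`): brute-force validation on
  tiny explicit systems — deterministic nearest-unvisited walks on a
  1-D line, exact multinomial mixing entropies, and literal bit-count
  encodings — used to check the closed forms by enumeration.

## CLI

One entry point with five subcommands:

```sh
# sequential entropy of one mole of pure monomers (prints S_r_JK = 11.5263)
rnaorder entropy --n 4 --N-mol 1 --L 1 --M 0 --p 1

# description-length complexity at the sweep base point
rnaorder complexity --n 4 --L 20 --M 10 --p 0.5 --N-mol 1 --json

# order/complexity trajectories (p, L or M swept; CSV, JSON or plot)
rnaorder sweep L --out sweep_L.csv
rnaorder sweep p --format json --out sweep_p.json --plot sweep_p.png

# mutation/selection evolution run (50 time units, events every 5)
rnaorder evolve --loss 0.3 --rate -0.01 --period 5 --duration 50 --out traj.csv

# brute-force oracle suite (pass/fail table, nonzero exit on failure)
rnaorder validate --seed 7
```

Parameters may also come from a YAML/JSON config file with keys
`n, r, N_units|N_moles, L, M, p, pk, a`; explicit flags override the
file, and the effective configuration is echoed to the log.

## Units

Entropies are computed dimensionless (units of the Boltzmann constant
k) and converted last; when `N` is one mole of units the J/K figure
coincides with J/(K·mol). Complexities are in bits, always accompanied
by a decimal logarithm that stays finite when the bit count overflows
double precision.
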