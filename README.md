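# filacol

Off-lattice simulation, image morphometry and likelihood-free inference
for filamentous yeast colonies.

Under nutrient stress, *Saccharomyces cerevisiae* cells switch from
compact bipolar ("sated") budding to elongated, end-to-end unipolar
("pseudohyphal") budding, and colonies grow filaments that radiate from
a compact Eden-like core. `filacol` links those cell-scale budding rules
to colony-scale morphology:

- **`filacol.geometry` / `filacol.simulate`** — a two-dimensional
  off-lattice agent-based model. Each cell is an ellipse (sated
  4.2 × 3 μm, pseudohyphal 6.7 × 1.9 μm) with four bud sites placed at
  the budding angle ±β about each pole. Growth is a sequence of budding
  events governed by five parameters
  θ = (n\*, p_a, p_sp, p_ps, γ): the colony-size fraction n\* at which
  pseudohyphal growth becomes possible, the sated-mother probability
  p_a, the sated→pseudohyphal daughter probability p_sp, the
  pseudohyphal→sated daughter probability p_ps, and the forking control
  γ. Volume exclusion aborts any event that would place a new cell's
  centre inside an existing cell.
- **`filacol.morphometry`** — three statistics of a binary colony mask:
  the radius ratio I_R = r_csr / r_max, the filamentous area ratio I_F
  (occupied fraction in the annulus [r_csr, r_max]), and the sub-branch
  count I_B (skeleton branch segments in the quadrant θ ∈ [π/2, π]).
  Here r_max is the maximum centroid-to-pixel distance and r_csr is
  where the radial occupancy density drops below
  ρ_csr = N / (π r_max²).
- **`filacol.inference`** — ABC-MCMC: a Metropolis–Hastings chain whose
  acceptance probability
  α = min{1, π(θ\*)/π(θ_i) · **1**[ρ(S(x), S̄) ≤ ε]} replaces the
  intractable likelihood with an indicator that the simulated colony's
  normalised statistics S(x) lie within ε of the observed replicate mean
  S̄ under the weighted distance
  ρ(S, S̄) = (1/3)·[Σ_i ((S_i − S̄_i)/(1 + S̄_i))²]^{1/2}.
  Independent Beta priors; Gaussian proposals tuned from pilot runs to a
  5–10% acceptance rate.
- **`filacol.fixtures`** — programmatic masks with known morphology
  (disks, disks with radial spikes, Y-filaments, random blobs) and
  simulated replicate sets, so the whole pipeline is testable without
  photographs.

The main entry points follow scikit-learn conventions:
`ColonySimulator` (`sample`), `ColonyMorphometry` (`transform`) and
`AbcMcmc` (`fit`, fitted attributes `samples_`, `acceptance_rate_`,
`ess_`).

## Worked example

```python
import numpy as np
from filacol import AbcMcmc, ColonyMorphometry, ColonySimulator
from filacol.fixtures import synthetic_replicate_set

# 1. simulate one colony and measure it
sim = ColonySimulator(n_star=0.67, p_a=0.14, p_sp=0.25, p_ps=0.58,
                      gamma=0.12, n_max=1000, random_state=0)
colony = sim.sample()
stats = ColonyMorphometry().transform([sim.sample_masks(1)[0]])
print(colony.n, colony.pseudohyphal_count(), stats.round(3))

# 2. recover the parameters from ten simulated replicates
theta_true = [0.67, 0.14, 0.25, 0.58, 0.12]
_, ref = synthetic_replicate_set(theta_true, n_rep=10, n_max=1000, seed=42)
sampler = AbcMcmc(n_max=1000, chain_length=2000, n_chains=3,
                  random_state=7).fit(ref)
print(np.round(sampler.posterior_mean_, 3), round(sampler.acceptance_rate_, 3))
```

The first block prints `1000 252 [[25. 0.253 0.503]]`: a 1000-cell
colony with 252 pseudohyphal cells, whose mask has 25 branch segments
in the counting quadrant, 25% of its area in the filamentous annulus,
and a compact core reaching 50% of the colony radius. The second block
prints `[0.594 0.299 0.535 0.467 0.273] 0.084`: the posterior mean and
the realised acceptance rate. The identifiable parameters are recovered
(n\* = 0.59 vs truth 0.67 and γ = 0.27 vs 0.12, both inside their 90%
credible intervals, which are wide at this reduced scale), the weakly
identified probabilities revert towards their priors, and the
acceptance rate sits in the tuned 5–10% band.

A command-line interface mirrors the library:

```sh
filacol simulate --params params.yaml --seed 1 --out run/
filacol stats --in run/ --out stats.csv
filacol infer --obs stats.csv --config abc.yaml --seed 1 --out abc/
filacol recover --theta 0.67,0.14,0.25,0.58,0.12 --out rec/
```

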