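# Methods

## The growth model

`filacol` simulates a two-dimensional, off-lattice colony of budding
yeast. A cell *i* is an ellipse with centre **m**ᵢ, half-length *a*ᵢ
along its axis, half-width *b*ᵢ, and orientation θᵢ (anticlockwise from
the x-axis). Its boundary is parameterised as

    x(φ) = m + (a cosφ cosθ − b sinφ sinθ, a cosφ sinθ + b sinφ cosθ),

with φ = 0 at the distal pole. Two fixed cell types are used:

| type | half-length a (μm) | half-width b (μm) | budding angle β | aspect ratio |
|---|---|---|---|---|
| sated | 4.2 | 3.0 | 7π/16 | 1.4 |
| pseudohyphal | 6.7 | 1.9 | π/16 | 3.5 |

The two types have areas π·a·b that differ by about 1%, which is why a
cell-count stopping rule is an acceptable proxy for colony area.
Each cell carries four bud sites, two flanking each pole at the
boundary parameter φ_β solving tan β = (b/a)·tan φ_β, computed in
closed form as φ_β = β + arctan((a−b)·tanβ / (b + a·tan²β)). A daughter
is oriented along the outward ray from the mother's centre through the
chosen site and placed so its proximal pole touches the site
(tangential contact; the model permits later partial overlap but starts
daughters without any). Cells never move, grow, change shape or die,
and time is not modelled: a simulation is a sequence of budding events.

A budding event is proposed as follows. While n/n_max ≤ n\*, the mother
is uniform over all cells and every daughter is sated (compact
Eden-like phase). Afterwards the mother is sated with probability p_a
(forced sated if no pseudohyphal cell exists yet), uniform within its
type. A sated mother produces a pseudohyphal daughter with probability
p_sp at any of its four free sites. A pseudohyphal mother buds only
from its two distal sites; if it has no pseudohyphal daughter yet, the
daughter is pseudohyphal (unipolar end-to-end extension); if it already
has one, then with probability γ the event is redirected to a uniformly
chosen branch tip (a pseudohyphal cell with no pseudohyphal daughter) —
the forking control — and otherwise the daughter is sated with
probability p_ps. A proposal is aborted, and the whole procedure
restarts with fresh draws, when the chosen mother has no free permitted
site, when a γ-redirect finds no eligible tip, when the new cell's
centre would fall strictly inside an existing cell (partial volume
exclusion: only the centre is tested, so overlap up to a half-cell is
allowed), or when the new cell's boundary would leave the domain.
Bud sites are single-use (a bud scar blocks reuse). A configurable cap
(default 10⁵) on consecutive aborted events turns a jammed colony into
a reported stall rather than a livelock.

Stopping is by cell count n_max, or alternatively by rasterised area:
growth continues until the occupied pixel count is within 5% of a
target (useful when matching an observed colony's size). The default
domain, 4000 × 4000 μm, is large enough that colonies at the scales
used here never touch the boundary.

Two engines implement the same event loop: a readable Python/NumPy
reference and a numba-compiled kernel used by default. They follow
identical logic and are each deterministic given the seed, but consume
different random streams, so seed-for-seed traces differ between
engines (never within one). The rasteriser (pixel occupied iff its
centre lies inside any cell, boundary inclusive) has compiled and NumPy
paths that agree exactly.

## Morphology statistics

For a binary mask with N occupied pixels, centroid at the mean occupied
coordinate and maximum centroid distance r_max, the reference density
ρ_csr = N/(π·r_max²) is the density the colony would have if its pixels
were spread uniformly over the disc of radius r_max. The CSR radius
r_csr is where the radial occupancy density (unit-pixel annuli) crosses
from ≥ ρ_csr to < ρ_csr, taking the outermost crossing and linearly
interpolating between annulus midpoints; because colony profiles
decrease outward the crossing is in practice unique. The statistics
are:

- I_R = r_csr/r_max — the fraction of the radius occupied by the
  compact core;
- I_F — the fraction of occupied pixels at distance ≥ r_csr (the
  filamentous annulus; the lower bound is closed);
- I_B — the number of skeleton branch segments in the quadrant
  θ ∈ [π/2, π] (anticlockwise from +x, y axis up — the image's top-left
  corner), restricted to r ∈ [r_csr, r_max]. The core (r < r_csr) is
  removed, the remainder thinned to an 8-connected one-pixel skeleton,
  branch-point pixels (≥ 3 skeleton neighbours) deleted, and the
  remaining connected components counted. Only one quadrant is counted
  to bound the cost of skeletonisation.

Two filters suppress discretisation artifacts in I_B: segments shorter
than 3 px are ignored, and a counted segment must extend at least 2 px
beyond r_csr radially. The second filter matters for nearly compact
masks: a perfect disc still leaves a sub-pixel sliver of pixels between
r_csr and r_max whose skeleton would otherwise contribute spurious
boundary arcs. Both thresholds are validated on constructed fixtures
(discs with a known number of spikes per quadrant, Y-shaped filaments)
whose true counts are known by construction.

All three statistics are ratios or counts: they are translation
invariant and robust to pixel resolution (verified at 1 and 2 px/μm).
Grayscale photographs are binarised by Otsu's global threshold with
polarity auto-detected from the image border; pre-binarised masks pass
through unchanged.

## ABC-MCMC inference

The five growth parameters θ = (n\*, p_a, p_sp, p_ps, γ) enter only
through the simulator, so the likelihood is intractable. `AbcMcmc`
samples an approximate posterior with a Metropolis–Hastings chain whose
acceptance probability is

    α = min{1, π(θ*)/π(θᵢ) · 1[ρ(S(x), S̄) ≤ ε]},

where x is one simulated colony at θ\*, S min–max normalises each of
(I_B, I_F, I_R) against the observed replicate vectors (so the three
statistics contribute comparably; simulated values may fall slightly
outside [0, 1]), S̄ is the normalised replicate mean, and

    ρ(S, S̄) = (1/3)·[Σᵢ ((Sᵢ − S̄ᵢ)/(1 + S̄ᵢ))²]^{1/2}.

The prefactor is implemented exactly as written (1/3 outside the root);
a `distance_prefactor="rms"` flag exposes the root-mean-square variant
for sensitivity checks. The Gaussian proposal is symmetric, so its
densities cancel. Proposals outside (0,1)⁵ are rejected through the
zero prior without running the simulator, and an infinite ε
short-circuits the simulator entirely, reducing the kernel to plain MH
on the prior — a cheap correctness check used in the tests. A simulator
stall is treated as a rejection with a logged warning.

Defaults follow the biology: priors Beta(5,2) for n\* (the transition
is late), Beta(2,5) for p_a and γ (post-transition growth is mostly
pseudohyphal, forking is common), and uninformative Beta(2,2) for p_sp
and p_ps. Chains start at the prior mean plus N(0, 0.02²) noise per
coordinate. `tune()` first measures distances of ~30 prior-predictive
simulations to set a loose starting ε (80th percentile), runs a pilot
chain to estimate the proposal covariance (scaled by 2.38²/5 and
jittered to positive definiteness; a degenerate pilot falls back to a
0.05² diagonal), then shrinks ε geometrically (factor 0.75) until a
300-iteration pilot accepts in the 5–10% band. Simulated colonies are
normalised with the same replicate min/max as the observations —
anything else would break comparability.

Per-parameter effective sample size uses the autocorrelation sum with
Geyer's initial-positive-sequence truncation (consecutive lag pairs are
accumulated until the first non-positive pair), clamped to [1, M]. On
white noise it recovers the chain length within a few percent; on an
AR(1) chain with coefficient 0.9 it matches M(1−φ)/(1+φ) within ~10%.

## Synthetic data and what the tests show

No colony photographs ship with the package. The fixture module
generates masks with known morphology — discs (compact, branchless),
discs with n evenly spaced radial spikes placed so the number falling
in the counting quadrant is known exactly, Y-shaped filaments (three
skeleton segments), and random blobs (a solid core with a speckled
sub-CSR halo, used for fuzzing and for reaching high I_F) — and
simulated replicate sets at known θ. These fixtures exercise every
code path and pin the statistics to construction-known values, but they
are idealisations: real photographs add uneven illumination, contact
artifacts and thresholding noise that only the Otsu fallback addresses.
Recovering θ from real images additionally depends on the observed
replicates' spread, which fixes the normalisation.

The end-to-end recovery study uses 10 simulated replicates at
θ_true = (0.67, 0.14, 0.25, 0.58, 0.12), colonies of n_max = 1000 cells
rasterised at 1 px/μm, tuning pilots of 300 iterations, and 3 chains of
2000 iterations — a problem size chosen so the full study runs in a few
minutes on one core. At this scale the 90% credible intervals for the
morphology-driving parameters n\* and γ contain the truth and the
acceptance rate lands in the tuned band; the remaining probabilities
are weakly identified (their posteriors stay close to their priors),
which mirrors how three summary statistics constrain five parameters.

## Known limitations

- Sated-only colonies (n\* = 1) are compact but not sharply bounded:
  because mothers are chosen uniformly over all cells, the rim is a
  broad stochastic front, and mean I_R at n_max = 1000 is ≈ 0.73
  (rising to ≈ 0.78 at n_max = 4000, independent of resolution). Model
  variants that select mothers on the periphery would sharpen the edge
  but change the model.
- The exclusion rule tests only the new cell's centre, so a later
  daughter may legally cover an earlier cell's centre; no mechanical
  relaxation or pushing is modelled.
- One simulated colony per MCMC iteration: the indicator is noisy, and
  chains need the 5–10% acceptance tuning to mix; ESS per 2000-iteration
  chain is in the tens, so production-quality posteriors need longer or
  more chains.
- Nutrient fields, diffusion-limited growth, cell mechanics and
  time-resolved dynamics are deliberately outside the model.
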