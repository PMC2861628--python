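# Methods

## The model

`mossyinfo` implements a feedforward model of how dentate-gyrus (DG)
granule cells, through their sparse and powerful mossy-fiber (MF)
projections, establish a new spatial representation in CA3. The model is
deliberately minimal: recurrent CA3 collaterals, perforant-path input,
theta/gamma dynamics, neurogenesis and CA1 are all outside its scope, and
everything CA3 receives besides the MF drive is absorbed into a Gaussian
noise term.

**Arena.** A square of side L = 20 grid units with periodic boundary
conditions (a flat torus), discretized into 20 × 20 bins for decoding and
occupancy statistics. The torus removes border effects; the largest
possible separation is (L/2)·√2 ≈ 14.1 grid units. A virtual rat performs
a persistent random walk: each time step it advances 0.5 grid units along
a heading perturbed by a wrapped-Gaussian angle of SD 0.2 rad. One step
nominally stands for half a theta cycle; the physical duration never
enters any computation.

**DG population.** Each of n_DG granule cells is active in the
environment with probability p = 0.033. Active units carry a number q of
place fields drawn from one of three laws with mean ν = 1.7: Poisson
(model A, the reference; q = 0 is possible), a discrete exponential
implemented as the geometric law on q ≥ 1 (model B), or exactly one field
(model C). Every field is an isotropic Gaussian bump of unit peak rate
β₀ = 1, truncated to zero beyond the radius R = √(f·A/π) where
f = 0.05 is the field-to-arena area ratio; the width is tied to the cut
as σ_f = R/2 (≈ 1.26 grid units), so the bump has fallen to e⁻² at the
truncation circle. Centers are uniform on the torus and a unit's rate is
the plain sum of its bumps — DG firing is noise-free and threshold-free.

**CA3 population.** Each of n_CA3 units receives a Bernoulli(C_MF/n_DG)
random subset of the DG axons (in-degree ≈ Poisson with mean C_MF = 50),
with uniform weights J = 1. The transfer function is threshold-linear
with unit gain,

    η_i(x) = [ Σ_j c_ij w_ij β_j(x) + ε_i − θ ]₊ ,

with ε_i ~ N(0, δ²), δ = 1, drawn fresh per unit and time step. The
threshold θ models feedback inhibition: at every time step it is adjusted
(vectorized bisection, tolerance 10⁻³) so that the population sparsity
a = ⟨η⟩²/⟨η²⟩ (Treves–Rolls) equals 0.1. A fixed-θ mode is provided for
comparison with the analytic θ(a) inversion; the two agree (the
fixed-θ run realizes a = 0.10 ± 0.02).

**Units and normalization.** Rates are dimensionless: β₀ = 1 fixes the
rate scale, J = 1 the synaptic scale, and δ = 1 is the noise SD in those
units. Where C_MF or p is swept, J is rescaled inversely (J = 50/C_MF,
J = 0.033/p) so the mean total MF drive per CA3 unit stays fixed.

## Decoding route

Position is decoded step by step from the rate vector of a sample of CA3
units by maximum-likelihood Euclidean template matching: templates are the
per-bin mean vectors from an *independent* trajectory of equal length (the
template pass never shares data with the decoded pass; bins unvisited in
the template pass — essentially impossible at standard run lengths — get
the population-mean template and a logged warning). Ties break to the
lowest bin index so decoding is deterministic given the rates.

Decoding events accumulate into the **full** localization matrix (counts
over 400 × 400 actual/decoded bin pairs; of order 160,000 events are
needed to sample it, hence 400,000-step runs at paper scale) and the
**simplified** matrix (counts over the 20 × 20 minimal-image displacement,
well sampled within a few thousand events). Plug-in information in bits:

* full:       I = H(decoded) − H(decoded | actual)
* simplified: I = H(decoded) − H(displacement)

so that each information measure plus its equivocation reconstructs the
same decoded-position entropy exactly — the bookkeeping that makes the two
routes comparable. The first-order limited-sampling correction
(Panzeri–Treves, with naive counting of occupied response bins) is
subtracted from both; the corrected value is floored at 0. The naive
variant is only consistent when response bins are adequately occupied,
which the permutation-null test respects by using a well-sampled fixture.

Information versus sample size is averaged over random unit subsets
(and over trajectory seeds) and fitted with the exponential-saturation
form I(n) = I_tot · (1 − exp(−n·I₁/I_tot)), whose parameters are the
initial per-unit slope I₁ and the asymptote I_tot. The fit is plain
least squares, initialized from the first and last points.

## Analytic route

With uniform weights and identical bumps, a CA3 unit's noise-free drive
depends only on the total number K of DG fields feeding it. The K-field
coefficients ψ_K — the compound law of a Poisson(λ = C_MF·p) number of
active inputs each carrying a model-A/B/C field count — are computed with
the exact compound-Poisson (Panjer) recursion, truncation auto-extended
until the tail mass is below 10⁻⁶. Model C reduces to Poisson(λ) exactly,
and models A and B converge to it as ν → 0 (ν → 1 for the geometric
model B) at fixed λν, which the tests check quantitatively.

For given K and field centers, the response channel
x → η = [s(x) − θ + ε]₊ is mixed discrete/continuous: an atom at zero of
weight Φ((θ − s(x))/δ) plus a truncated Gaussian density. The single-unit
information, response entropy and equivocation are evaluated with the atom
treated exactly and the continuous branch integrated on a uniform η grid
(241 points by default; doubling changes the result by < 1%), the spatial
integral on a grid of 40² points (32² in the desk profile; the standard
value moves by < 0.1% between 32² and 48²). Field centers are averaged by
seeded Monte Carlo — 2,000 configurations per K by default, 200–300 in
the desk profile (SE ≈ 0.5%) — with per-(K, configuration) random streams
so that parameter comparisons share draws and Monte-Carlo noise cancels.
Entropy − equivocation = information holds to machine precision per
configuration by construction. Only the first-order (single-unit) term is
computed; population information is reported at most as N times it, and
the higher-order correlation corrections are explicitly not implemented.

The sparsity–threshold relation a(θ) is evaluated over the same quenched
ensemble from the closed first/second moments of the rectified Gaussian,
using the fact that a bump seen from a uniform point is zero with
probability 1 − f and exp(−d²/2σ_f²) with d² uniform on (0, R²) otherwise;
a(θ) is strictly decreasing and is inverted by bisection to |a − a*| < 10⁻³.
θ(0.1) rises with J over the moderate range J ≤ 4; at much stronger input
the rare strong signals dominate ⟨η²⟩ and the relation flattens.

In the θ → −∞ limit the rectification never engages and the unit is
linear; at weak signal the information approaches the closed spatial
signal-to-noise form ½·log₂(1 + Var_x(s)/δ²), ψ-averaged over the same
center draws. The 2% agreement check runs at J = 0.1 because the closed
form is a low-SNR result; at standard J the linear value differs from the
thresholded one by design.

## Plasticity and degraded cues

MF plasticity uses a postsynaptically gated relaxation: for units with
η_i > 0, each existing connection moves as w_ij ← w_ij + γ·η_i·(β_j − w_ij),
clipped at 0; anatomy is never modified and γ = 0 is the identity. The
rule is bounded, has β_j as its fixed point under repeated pairing, and
spans "minor modification" to "major restructuring" as γ grows. It is an
explicit stand-in — no claim is made about the biophysics of MF synapses.
Training runs the standard per-step-threshold dynamics along a trajectory
(100,000 steps at paper scale, 20,000 in the desk profile); connections
from DG units silent in the environment simply decay, which the trainer
tracks with a lazily accumulated per-row multiplier for speed (verified
bit-compatible with the explicit one-step rule).

Cue degradation silences a random subset of the normally active DG units
for the whole decode pass; templates are built from the intact cue, so the
measurement asks how much of the stored map is recovered from a partial
input.

## Field census

The fraction of CA3 units with a place field (and with more than one) is
measured on the noise-free drive at the bin centers: a unit has a field
where that drive exceeds the run's mean threshold on a torus-connected
component of at least 3 bins (4-neighbour adjacency). The 3-bin floor
discards speckle; a genuine field at these parameters covers ≈ 20 bins.

## Scale profiles and what desk runs show

The `paper` profile is 15,000 DG × 500 CA3 units with 400,000-step
trajectories; the `desk` profile (5,000 × 200, 100,000 steps, sample sizes
1–50 with 8 subsets each, 3 trajectory seeds) keeps every quenched
statistic (λ, ψ_K, sparsity) identical and is what the test suite and the
acceptance script run. The connectivity sweep in the tests is scaled
further (4,000 × 150, 30,000 steps, 5 seeds) and checks orderings as
seed-averaged statements.

Two desk-scale caveats, visible in the numbers the suite itself computes:

* With 100,000 events the 160,000-cell full matrix is undersampled; the
  first-order bias correction removes most but not all of the sampling
  bias, and small-sample points (n = 1, 2) retain a visible residual.
  This is the same effect the model itself exhibits as "dark information"
  — the maximum-likelihood quantized matrix carries more measured
  information than the smooth channel probabilities — so desk-scale
  decoded values should be read as measurements of that construction, not
  as channel capacities.
* Under the unit normalization (β₀ = J = δ = 1, σ_f = R/2) the per-step
  signal-to-noise is modest: single-step decoding is noise-dominated at
  standard parameters, the decoded-position entropy of small samples
  stays well below log₂400, and the information-versus-connectivity
  optimum sits near C_MF ≈ 8 — at the edge of, rather than inside, the
  sweep grid {5, 15, 50, 150, 500}. The orderings that do not depend on
  the absolute signal scale (ν-invariance at fixed λν, equivalence of
  C_MF and p in the analytic route, full ≥ simplified information,
  sparsity control, the one-third field fraction near the optimum) are
  robust to this choice.

## What the synthetic generator does and does not emulate

The generator reproduces the statistical structure the model assumes:
multi-field DG units with Poisson/exponential/single-field counts, uniform
field centers, Bernoulli MF connectivity, Gaussian rate noise, a uniform
occupancy random walk. It does not emulate real rodent behaviour
(non-uniform occupancy, speed modulation), spiking variability, theta
phase, grid-cell-driven DG activation, or any plasticity beyond the model
rule. Passing tests therefore validate the model's internal claims, not
agreement with recorded data.

## Numerical choices

* Thresholds: per-step bisection, 34 halvings per step (batch mode),
  realized sparsity within 10⁻³ of target; degenerate (constant) inputs
  raise an explicit unattainable-sparsity error.
* Decoding ties: lowest bin index, so noiseless tests are deterministic.
* ψ_K truncation: K_max doubles from 30 until tail < 10⁻⁶ (hard cap 4096);
  low-order terms are never clipped — only the final information is
  floored at 0.
* All randomness flows from explicit seeds through `numpy` `SeedSequence`
  spawning; sessions are bit-reproducible from (parameters, seed).
* Rates are held in float32 for long sessions (memory), all information
  arithmetic in float64.
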