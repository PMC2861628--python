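# mossyinfo

How much spatial information can the dentate gyrus (DG) impart on a new
CA3 representation through its sparse, powerful mossy-fiber projections?
`mossyinfo` is a simulation and analysis toolkit for that question,
aimed at computational neuroscientists studying hippocampal spatial
coding. It implements a feedforward threshold-linear model in which DG
granule cells with multiple Gaussian place fields drive noisy CA3 units
under tight sparsity control, and measures the information the resulting
CA3 activity carries about the animal's position by two complementary
routes:

1. **Decoding route** — a virtual rat explores a toroidal arena; position
   is decoded per time step from samples of CA3 units by
   maximum-likelihood Euclidean template matching, and mutual information
   is extracted from localization ("confusion") matrices in two forms:
   the *full* matrix over (actual, decoded) bin pairs, and the
   *simplified* matrix over their displacement, which assumes
   translation-invariant errors. The gap between the two is the model's
   "dark information": the share of spatial information invisible to the
   translation-invariant summary.
2. **Analytic route** — the single-unit information

   I₁ = ⟨ ∫ dx/A ∫ dη p(η|x) log₂[p(η|x)/p(η)] ⟩,

   with the quenched average over connectivity, field counts and field
   centers reduced to an expansion in the total number K of DG fields
   feeding a unit, weighted by compound-Poisson coefficients ψ_K
   (Poisson number of active inputs, model-dependent fields per input).
   The mixed discrete/continuous response (an atom at zero rate plus a
   truncated Gaussian) is integrated numerically with the atom exact.

The model's core quantities: CA3 rates η_i(x) = [Σ_j c_ij w_ij β_j(x) +
ε_i − θ]₊ with Gaussian noise ε and a threshold θ adjusted every step so
the Treves–Rolls sparsity a = ⟨η⟩²/⟨η²⟩ stays at 0.1; DG rates β_j(x) are
sums of truncated Gaussian bumps. Standard parameters: 15,000 DG units
(p = 0.033 active, ν = 1.7 fields each on average), 500 CA3 units with
C_MF = 50 mossy-fiber inputs of strength J = 1, noise SD δ = 1.
See `docs/methods.md` for the full account.

## Worked example

Simulate a desk-scale standard session (5,000 DG × 200 CA3 units,
100,000-step trajectory), decode position from unit samples, and compare
with the analytic estimate:

```python
import numpy as np
from mossyinfo import (
    AnalyticParams, CA3Params, DGParams, SessionParams,
    fit_info_curve, info_vs_sample_size, single_unit_info,
)
from mossyinfo.decoding import average_curve
from mossyinfo.simulate import run_session

sp = SessionParams(dg=DGParams(n_dg=5000), ca3=CA3Params(n_ca3=200),
                   n_steps=100_000)
sess = run_session(sp, seed=42)
print(f"realized CA3 sparsity: {sess.mean_sparsity:.4f}")

df = info_vs_sample_size(sess.rates, sess.actual_bins, sess.templates,
                         sizes=(1, 2, 5, 10, 20, 50), n_samples=8,
                         side_bins=20, rng_seed=1)
full = average_curve(df, "full")
simp = average_curve(df, "simplified")
i1, i_tot = fit_info_curve(full.n, full.bits)
print("n:          ", full.n)
print("full bits:  ", np.round(full.bits, 3))
print("simpl bits: ", np.round(simp.bits, 3))
print(f"fit: I1 = {i1:.3f} bits/unit, I_tot = {i_tot:.2f} bits")

analytic = single_unit_info(AnalyticParams(n_configs=250, grid_points=32))
print(f"analytic single-unit information: {analytic:.4f} bits")
```

Output (seed 42):

```
realized CA3 sparsity: 0.1000
n:           [ 1  2  5 10 20 50]
full bits:   [0.169 0.061 0.125 0.271 0.434 0.748]
simpl bits:  [0. 0. 0. 0. 0. 0.]
fit: I1 = 0.031 bits/unit, I_tot = 0.91 bits
analytic single-unit information: 0.0163 bits
```

Reading the numbers: the inhibition-mimicking threshold holds the
population sparsity exactly at its target; full-matrix information grows
sublinearly with sample size (0.27 bits from 10 units) while the
displacement-based estimate recovers none of it at these noise-dominated
standard parameters — the dark-information gap in its extreme form; and
the fitted per-unit slope (0.031 bits) exceeds the analytic single-unit
value (0.0163 bits) roughly twofold, the signature of the
maximum-likelihood quantized matrix carrying more measured information
than the smooth channel probabilities.

## Experiments and CLI

Each headline experiment is a library function
(`mossyinfo.experiments.run_sweep_connectivity`, `run_dark_information`,
`run_plasticity`, `run_degraded_cue`, ...) returning a long-format
`pandas.DataFrame` with full seed provenance, and a matching CLI
subcommand:

```sh
mossyinfo sweep-connectivity --profile desk --seed 0 --out results/
mossyinfo dark-information --config overrides.yaml --out results/
```

`--profile paper` uses the full network scale (15,000 × 500, 400,000
steps); `desk` is the reduced profile used throughout the tests.

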