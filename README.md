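# acesfit

Moment-based inference of gene-expression mechanism from protein
distributions.

Clonal populations of cells expressing the same gene show broad,
reproducible distributions of protein copy number. Those distributions are
shaped by six biochemical rate constants — promoter activation and
inactivation (k_on, k_off), transcription from the active promoter (k_r),
translation (k_p), and RNA and protein degradation (γ_r, γ_p) — but
inverting a measured distribution into rates is hard: solutions are
massively degenerate, and the classical analytical shortcuts only apply in
narrow parameter regimes. This package implements an assumption-free route
for that inversion, aimed at anyone analysing flow-cytometry or imaging
snapshots of reporter-gene expression:

* **Forward:** the steady-state protein mean M, variance V, and third and
  fourth central moments μ₃, μ₄ of the two-state (telegraph) model are
  computed *exactly*. Because every reaction propensity is linear, the
  promoter-partial moments E[s·mⁱ·pʲ] and totals E[mⁱ·pʲ] (1 ≤ i+j ≤ 4)
  satisfy a closed linear system of 28 equations — no moment-closure
  approximation — with the promoter occupancy p_on = k_on/(k_on+k_off)
  substituted in closed form.
* **Inverse (ACES):** an analytically constrained exhaustive search over a
  log-spaced grid of rate space. The closed-form mean

      M = k_r·k_p·k_on / (γ_r·γ_p·(k_on + k_off))

  is monotone in every rate, so each assignment analytically brackets the
  admissible interval of the next rate, and the last free rate is solved
  exactly — every candidate reaching the moment screen already matches the
  mean. Candidates are then screened on V, μ₃, μ₄ (cheapest first) at a 1%
  relative tolerance, and *all* survivors are returned: the ensemble, not a
  point estimate, is the result.
* **Interpretation:** median-log-distance (MD) fit summaries over the six
  rates and eight mechanistic ratios (promoter occupancy, burst size and
  frequency, mean RNA, proteins per RNA, the gamma-model shape/scale
  ratios…), maximally-distant solution pairs, Jensen–Shannon divergence of
  count histograms, gamma/Friedman reference estimators, an exact Gillespie
  simulator for validation, and builders for regime-spanning test
  libraries.

## Worked example

```python
import numpy as np
from acesfit import (CDRCSet, CDRCRanges, ACESConfig,
                     protein_central_moments, aces_fit, summarize_ensemble)

truth = CDRCSet(k_on=0.21, k_off=0.34, k_r=18.0, k_p=0.90, g_r=1.9, g_p=0.031)
target = protein_central_moments(truth)           # exact forward moments
print(np.round([target.M, target.V, target.skewness, target.kurtosis], 3))

ranges = CDRCRanges(k_on=(0.05, 5.0), k_off=(0.05, 5.0), k_r=(0.5, 50.0),
                    k_p=(0.1, 10.0), g_r=(0.1, 10.0), g_p=(0.005, 0.5))
ensemble = aces_fit(target, ACESConfig(ranges=ranges, resolution=24))
summary = summarize_ensemble(ensemble, truth)
print(len(ensemble), ensemble.n_tested)
print(round(summary.md["burst_size"], 3), summary.success["burst_size"])
```

prints

```
[1.050160e+02 1.103232e+03 3.030000e-01 2.903000e+00]
15 4569763
0.289 True
```

Read: a gene with mean ≈ 105 proteins, variance ≈ 1103 and mild right skew
admits 15 distinct rate-constant sets out of ~4.6 million mean-consistent
candidates screened — and the transcriptional burst size k_r/k_off is
constrained to within a third of a decade across the whole ensemble
(MD ≈ 0.29, a successful fit), which is exactly the kind of mechanistic
conclusion the ensemble view is for. A `fit` CLI subcommand (plus `moments`, `simulate`, `analyze`,
`compare`, `library`, `fixtures`) exposes the same pipeline on TSV/YAML
files: see `acesfit --help`.

## Layout

| module | contents |
| --- | --- |
| `acesfit.model` | rate-set / range / moment / ratio types and validation |
| `acesfit.moments` | the 28-equation closed moment system and exact solver |
| `acesfit.search` | ACES: bound propagation, grid enumeration, moment screen |
| `acesfit.simulate` | exact Gillespie sampling of cell populations |
| `acesfit.ensemble` | MD fitness, success calls, distant pairs, library tables |
| `acesfit.metrics` | KL/JSD, log-Euclidean distances, gamma/Friedman tools |
| `acesfit.library` | regime-spanning Cartesian libraries + mean filter |
| `acesfit.fixtures` | deterministic planted-truth and regime-panel generators |
| `acesfit.io`, `acesfit.cli` | TSV/YAML/JSON round-trips and the CLI |

`docs/methods.md` documents the model, the algorithm, the numerical
choices and their limitations.
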