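# svfcs

Fluorescence correlation spectroscopy (FCS) analysis of transient protein
binding to immobilized synaptic-vesicle layers.

## The problem

Soluble presynaptic proteins (synapsin, α-synuclein, endocytosis cofactors,
…) are strongly enriched in the synaptic bouton, and a leading explanation
is that the dense cluster of synaptic vesicles (SVs) binds them transiently.
A minimalist way to test this is to immobilize purified SVs as a 2D layer on
a coverslip and measure the mobility of fluorescently tagged proteins on top
of the layer by single-point FCS: a protein that binds shows, besides its
fast freely diffusing pool, a second slow pool whose diffusion coefficient
and number fraction quantify the interaction.

`svfcs` implements the complete quantitative chain for this experiment:

* **ACF models** — the single-species 3D-diffusion autocorrelation

  G(τ) = (γ/N) · 1/(1 + τ/τ_D) · 1/√(1 + (τ/τ_D)(w₀/z₀)²),  τ_D = w₀²/(4D)

  with amplitude G(0) = γ/N (γ = 0.35 for the 3D-Gaussian confocal volume),
  and the number-weighted two-species sum
  G₂(τ) = γ/N² · (N₁G₁(τ) + N₂G₂(τ)) for a fast free pool and a slow bound
  pool; bound fraction p_b = N₂/(N₁+N₂).
* **Correlator** — a multi-tau estimator (quasi-logarithmic lags,
  progressive rebinning, symmetric normalization) emulating a hardware
  correlator card, validated against a brute-force linear-lag oracle.
* **Synthetic data** — Brownian-dynamics simulation of emitters with
  two-state (free/bound) Markov switching in a periodic box around the
  confocal volume; fast direct synthesis of noisy ACF curves; STED-like
  spot images of vesicle patterns. Presets encode the measured operating
  points of eleven synaptic proteins and two control antibodies.
* **Fitting** — Levenberg–Marquardt-style nonlinear least squares with
  multi-start over diffusion times, observation-volume calibration from a
  reference dye (w₀ = √(4·D_ref·τ_D)), an F-test model selector with an
  effective-sample-size correction, and an aggregate-spike exclusion screen.
* **Energetics** — two-state Boltzmann analysis: ΔE = E_f − E_b =
  k_BT·ln(p_b/(1−p_b)), E_b = 3/2 − ln(p_b/(1−p_b)) in k_BT (E_f = 3/2 k_BT
  from three translational degrees of freedom), transition-rate ratio
  r_fb/r_bf = p_b/p_f.
* **Vesicle density** — difference-of-Gaussians bandpass, robust
  thresholding, subpixel spot detection, areal density and
  nearest-neighbour spacing.
* **Stats** — Mann–Whitney U, Kruskal–Wallis with Dunn or
  Tukey-HSD-on-ranks post-hoc tests.

## Worked example

Recover the binding parameters of an α-synuclein-like condition on a
vesicle pattern (generating values: D_free = 67 µm²/s, D_bound = 4 µm²/s,
15% bound):

```python
import numpy as np
from svfcs import (ObservationVolume, TwoStateEnergetics,
                   fit_two_component, preset_params, synthesize_acf)

vol = ObservationVolume.default()          # w0 = 310 nm, z0/w0 = 5, gamma = 0.35
params = preset_params("alpha_synuclein_on_sv", vol)
curves = synthesize_acf(params, vol, noise_fraction=0.02, n_curves=25, seed=2)
fits = [fit_two_component(c, vol) for c in curves]

print(np.mean([f.d_free for f in fits]))   # 65.5  um^2/s  (fast, free pool)
print(np.mean([f.d_bound for f in fits]))  # 3.93  um^2/s  (slow, bound pool)
print(np.mean([f.pct_bound for f in fits]))# 14.7  % bound

e = TwoStateEnergetics.from_bound_fraction(0.147)
print(e.delta_E)                           # -1.76 kBT  (free state favoured)
print(e.E_b)                               #  3.26 kBT  (bound-state energy)
```

The slow pool is ~17× slower than the free pool, and the negative ΔE says
binding is transient: the protein spends most of its time free, consistent
with an entropy-dominated interaction.

More narrative scripts live in `examples/` (bulk diffusion, the full
Brownian-dynamics → correlator → fit chain, vesicle-density quantification,
and the multi-condition pipeline). A thin CLI mirrors the stages:
`svfcs simulate-acf | correlate | calibrate | fit | summarize | energetics |
density | stats | run`.

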