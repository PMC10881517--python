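# tipbond

Bond mechanics of the inner-ear tip link: slip-catch-slip kinetics,
force-clamp survival analysis, and the emergence of an ideal bond from
cross-linked catch bonds.

Tip links — heterotetrameric filaments of cadherin-23 and
protocadherin-15 connecting adjacent stereocilia — convey sound-induced
tension to mechanotransduction channels. Force-clamp spectroscopy shows
that the *individual* cadherin binding interface is a slip-catch-slip
bond: its mean lifetime first falls with force, rises again above a first
critical force F_C1 (≈58 pN) to a maximum near a second critical force
F_C2, then falls once more. The assembled *complex* instead behaves as a
slip-ideal-slip bond, with a force-insensitive plateau in the ~36–70 pN
band. `tipbond` implements the models and analysis used to establish and
explain this picture, for anyone who analyses force-clamp lifetime data
or models adhesion-bond clusters under load.

## What is in the box

- **`tipbond.kinetics`** — the modified sliding-rebinding model. Four
  occupation probabilities (P11, P10, P01, P00) evolve under Bell-type
  rupture rates k₋₁(f) = k₋₁⁰ exp(f·x_β/k_BT), k₋₂(f) = 2k₋₁⁰
  exp(f·x_β/2k_BT), with a force-dependent rebinding probability
  P_n = {½[1 − cos(πF/F_C2)]}ⁿ on F_C1 ≤ F ≤ F_C2 (0 below, 1 above).
  Survival curves come from the matrix exponential, mean lifetimes from
  the exact mean first-passage time, and an exact Gillespie sampler
  provides stochastic lifetimes. Mutant (pivot-less) interfaces set
  P_n ≡ 0 and are pure slip bonds.
- **`tipbond.unfolding`** — unfolding-augmented survival: Bell-model
  domain unfolding (P_iu = 1 − exp(−k_iu t)) of the two dominant step
  classes (~5 and ~12 nm), count-weighted into a total unfolding
  probability P_U that damps the dissociated state, P00u = P_U·P00.
- **`tipbond.clamp`** — the experimental pipeline: product-limit survival
  estimation with right censoring, mono/bi-exponential fits with F-test
  model selection, Bell fits ⟨τ⟩ = τ₀ exp(−f/f*) of slip regions and
  constant fits of ideal regions, unfolding-step detection in
  force/height traces, and Gaussian-mixture step-height fitting.
- **`tipbond.fitting`** — multistart weighted least-squares fits of the
  kinetic model (with or without the unfolding augmentation) to
  lifetime-force curves, plus an end-to-end parameter-recovery harness.
- **`tipbond.langevin`** — a 2D underdamped Langevin simulator of
  semiflexible bead-spring filaments (harmonic stretching, discrete
  bending, WCA excluded volume) coupled by breakable springs whose
  rupture rate is catch-slip:
  ω_off(f) = ω₀⁽¹⁾exp(f/f_d⁽¹⁾) + ω₀⁽²⁾exp(−f/f_d⁽²⁾).
  Dimeric and tetrameric (free or cross-linked) arrangements measure
  attachment lifetimes under constant pulling force; cross-linking
  flattens the catch region into an ideal-like plateau.
- **`tipbond.synth`** — the instrument surrogate: Gillespie lifetime
  datasets (with the high-force short-lived second component), clamp
  traces with force spikes and height steps, and Poisson unfolding
  counts.

Published parameter sets (interface WT/mutant, the four Cdh23 length
variants, unfolding classes, step-height means, complex slip/ideal-region
fits) ship in `tipbond.params`.

## Worked example

```sh
python examples/lifetime_force_curves.py
```

prints the model lifetime-force curves at the published interface
parameters (excerpt):

```
force_pN   tau_wt_s   tau_mutant_s
       5     6.4933         6.1444
      30     3.0524         4.1445
      60     2.0912         2.6678
      95     3.9877         1.6678
     150     0.5963         0.8704

Wild type: lifetime rises again above the first critical force (58 pN)
and peaks near 95 pN — the catch regime.
Mutant: lifetime only decreases with force — the catch regime is lost.
```

The wild-type lifetime is non-monotonic — the catch signature — while the
R113G-like mutant only decays. The other scripts in `examples/` walk
through survival analysis with F-test model selection, step detection and
mixture fitting, full model fitting on a synthetic campaign, the
unfolding adjustment, and a small filament-simulation ensemble. A thin
CLI (`tipbond kinetics|unfolding|analyze|fit|langevin|synth`) wraps the
same functions for shell use.

## Method notes

See `docs/methods.md` for the model equations and assumptions, the
numerical choices (solvers, integrator, thresholds), what the synthetic
generator does and does not emulate, and known limitations.
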