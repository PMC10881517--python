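# Methods

## The sliding-rebinding kinetic model

A doubly bonded binding interface is described by four occupation
probabilities: P11 (both pseudo-bonds formed), P10 (one broken), P01 (a
re-formed single-bond state reached when tension reorients the interface
instead of breaking it) and the absorbing dissociated state P00. The
master equation is

    dP11/dt = 2 k+1 P10 + k+2 P01 − k−2 P11
    dP10/dt = k−2 P11 − 2 (k+1 + k−1) P10
    dP01/dt = 2 P_n k−1 P10 − (k+2 + k−1) P01
    dP00/dt = 2 (1 − P_n) k−1 P10 + k−1 P01

with Bell-model rupture rates k−1(f) = k−1⁰ exp(f·x_β/k_BT) for a single
bond carrying the full load and k−2(f) = 2 k−1⁰ exp(f·x_β/2·k_BT) for the
pair sharing it. The rebinding probability is a cosine switch,

    P_n = 0                                F < F_C1
    P_n = {½ [1 − cos(π F / F_C2)]}ⁿ       F_C1 ≤ F ≤ F_C2
    P_n = 1                                F > F_C2,

implemented exactly as stated, including the discontinuity at F_C1 (the
cosine branch need not vanish there). Survival is S(t) = P11 + P10 + P01
= 1 − P00. Slip behaviour at low force, catch behaviour between the
critical forces and slip again above F_C2 follow from the competition
between Bell-accelerated rupture and force-enabled rebinding. Mutant
interfaces that have lost the pivot contact have P_n ≡ 0 at every force;
this restriction reproduces the separately stated mutant rate equations
while preserving probability conservation.

Model assumptions worth keeping in mind: rates are held at the clamp
force (no loading-rate effects), the re-formed interface has the same
kinetics as the original, and the initial condition is the fully bound
state, P11(0) = 1.

### Numerics

The master equation is linear with constant coefficients at a clamped
force, so survival curves are evaluated with the matrix exponential of
the 4×4 generator (columns sum to zero; conservation holds to machine
precision, far inside the 1e−8 documented tolerance). The default mean
lifetime is the exact integral of the survival curve, computed as the
mean first-passage time −1ᵀM⁻¹x₀ of the 3×3 transient block — no
quadrature error, no truncation. Because the experimental lifetime is
obtained by fitting survival probabilities with an exponential, an
"expfit" estimator (single-exponential fit of the model curve over five
mean lifetimes) is provided as an alternative; for near-exponential decays
the two agree closely, and both are available in fitting workflows.

The stochastic oracle is a direct-method Gillespie sampler of the same
chain (two random numbers per event). It is used to cross-validate the
deterministic solver (Kolmogorov–Smirnov distance of the empirical
survival against the master-equation curve below 0.02 at n = 10⁴) and to
drive the synthetic-data generator.

### Parameters and units

Rates are in 1/s, forces in pN, distances in Å. The thermal energy
defaults to k_BT = 41.14 pN·Å (4.114 pN·nm, 298 K) and is exposed as a
parameter. The first critical force is not identifiable from the
published parameter tables; it defaults to the experimentally stated
58 pN and can be freed under the constraint 0 < F_C1 < F_C2 (the choice
is recorded in every fit result).

## Unfolding-augmented survival

Long constructs unfold extracellular domains before dissociating. Each
step class i unfolds with Bell kinetics k_iu(f) = k_iu⁰ exp(f·x_β^iu/k_BT)
and probability P_iu(t) = 1 − exp(−k_iu t). Only the two dominant classes
(~5 nm and ~12 nm) enter the total unfolding probability, weighted by the
observed per-force counts n₁, n₂:

    P_U = (n₁ P_1u + n₂ P_2u) / (n₁ + n₂),     P00u = P_U · P00.

The adjusted survival 1 − P00u dominates the bare survival pointwise —
unfolding dissipates interface load and extends survival. P_U is
evaluated on the same time grid as P00 (consistent reading of the
augmentation); a scalar mode evaluating P_U at the bare mean lifetime is
provided for sensitivity checks. The adjusted mean lifetime has a closed
form: with S(t) = Σ aᵢ e^{λᵢt} from the eigenmodes of the transient block
and U(t) = w₁e^{−k₁t} + w₂e^{−k₂t}, the integral of S + U − U·S is
evaluated analytically. Both class rates must be positive, otherwise the
adjusted survival never decays (a structural property of the
augmentation, which pins survival at 1 when P_U = 0). The per-force
counts have no prescribed functional form and are taken as tabular input;
the synthetic generator emits Poisson counts with Bell-probability means.

## Force-clamp analysis pipeline

Survival probabilities are estimated with the product-limit
(Kaplan–Meier) estimator; events that outlive the clamp window (10 s, or
20 s for the complex protocol) are right-censored. With no censoring the
estimator reduces to the naive surviving fraction. Mono- and
bi-exponential decays are fit to the survival curve by least squares
(mirroring the experimental procedure of fitting survival probabilities
rather than maximising a likelihood on lifetimes), with time constants
capped at 100× the observation window — beyond that they are not
identifiable. Model choice uses the F-test on the nested pair,
F = [(RSS₁−RSS₂)/(dof₁−dof₂)] / [RSS₂/dof₂], selecting the
bi-exponential at p < 0.05 by default.

Slip regions of lifetime-force curves are fit with ⟨τ⟩ = τ₀ exp(−f/f*),
ideal regions with a constant. The percent fit error is defined here as
100 × RMS residual / mean fitted value over the window (the source
analyses report percentages without stating a formula). Region boundaries
are user-supplied force intervals; no automatic boundary selection is
attempted.

Step detection: unfolding events appear as brief force spikes (~0.16 s)
with a concurrent discrete height gain. The detector estimates the force
noise scale from positive residuals only (spikes are one-sided), flags
contiguous runs of at least 3 samples below setpoint − 3σ, merges runs
closer than 10 ms, and measures the height gain as the difference of
50 ms height medians before and after the run (read inside the dip when
the spike is truncated by the end of the trace). All thresholds are
arguments. Under the generator's default noise the detector recovers
≥95% of ~5 nm steps with a false-positive rate below 1% per trace;
spikes overlapping in time are intrinsically unresolvable and are
reported as one event. Step-height distributions are summarised with
Gaussian mixtures (EM, 10 restarts); component collapse is flagged
rather than silently accepted.

## Model fitting

The sliding-rebinding fit minimises weighted residuals of mean lifetimes
against a measured curve — optionally log-lifetimes, which keeps points
commensurate when lifetimes span orders of magnitude across the force
range (the recovery harness defaults to the log objective for this
reason). Wild-type fits free {k−1⁰, x_β, k+1, k+2, F_C2, n}; mutant fits
free {k−1⁰, x_β, k+1}. A 16-point Latin-hypercube multistart (log-spaced
for rate-like parameters, deterministic under the seed) guards against
local minima; the best start wins. Standard errors come from the Jacobian
at the optimum, and the full parameter correlation matrix is always
reported: lifetime-force curves constrain the rebinding pathway only
weakly, and the k+1/k+2 correlation is routinely large — point estimates
of those two parameters should not be over-read. The mutant model is the
P_n ≡ 0 restriction of the wild type, so its best RSS can never beat the
wild-type fit on the same data; the test suite checks this nesting.

The end-to-end recovery harness simulates a full campaign (Gillespie
lifetimes → product-limit survival → exponential lifetime → curve → model
fit) and reports per-parameter bias, spread and RMSE. At the experimental
scale (60 lifetimes per force over the seven clamp forces, 20 replicates)
the intrinsic off-rate and transition distance are recovered within two
standard deviations of their generating values.

## Coarse-grained filament simulation

Each filament is a 2D chain of N = 35 beads with bond length σ:
stretching energy Σ A/2σ (bᵢ − σt̂ᵢ)², bending energy Σ κ/2σ (t̂ᵢ₊₁ −
t̂ᵢ)², and WCA repulsion 4ε[(σ/r)¹² − (σ/r)⁶ + ¼] below 2^{1/6}σ between
all non-bonded pairs. Defaults (reduced units: lengths in σ, energies in
k_BT, time in τ = ασ²/k_BT): A = 5×10³, κ = 5.1 — the rigidity parameter
u = L/λ = 3.33 with λ = 2κ/k_BT in 2D — ε = 1 (the energy scale is not
specified by the source model; one k_BT is the conventional choice),
k_m = 3×10⁻³ A/σ = 15 for the inter-filament springs, and catch-slip
detachment ω_off(f) = ω₀⁽¹⁾e^{f/f_d1} + ω₀⁽²⁾e^{−f/f_d2} with ω₀⁽¹⁾ =
4×10⁻⁶, ω₀⁽²⁾ = 0.1, f_d1 = 5, f_d2 = 10 — rate minimum at f* =
ln(12500)/0.3 ≈ 31.4 k_BT/σ per bond.

Dynamics are underdamped Langevin (unit mass, friction α = 1) integrated
with the BAOAB splitting at δt = 10⁻³τ; the noise satisfies
⟨ηᵢ(t)ηⱼ(t′)⟩ = 2αk_BT δᵢⱼ δ(t−t′). Velocities start Maxwell–Boltzmann
and each run is equilibrated (rupture disabled) before the clock starts.
A Verlet neighbour list (0.5σ skin, rebuilt every 20 steps — far more
often than the ~25σ a thermal bead would need to drift to defeat the
skin) keeps the WCA cost linear. Surviving bonds rupture with per-step
probability 1 − exp(−ω_off(f)δt), valid since ω_off·δt ≪ 1 at the
defaults; ruptured bonds never re-form. Trajectories are bitwise
reproducible under a fixed seed.

Arrangements: the dimer tethers one filament at its first bead and bonds
its last n_b = 10 beads to the first n_b beads of a second filament
pulled at the far end along +x (bead placement is not prescribed by the
source; a 10-bond consecutive overlap of rest length σ is the default and
configurable). The free tetramer stacks two mirror-image dimers with the
pulled filaments adjacent, holds the two pulled ends together with a
stiff permanent spring, and splits the external force equally between
them. The cross-linked tetramer adds three permanent springs of stiffness
k_m: the anchored pair is tied near the anchor (PICA-like) and adjacent
to the bonded region (EC3-like — EC3 sits three domains from the binding
interface, so the lateral contact belongs next to the bonded overlap, not
mid-chain), and the pulled pair is tied adjacent to the bonded region
(EC1-like); together with the held-together pulled ends, each lateral
pair is connected near both of its ends and moves as a unit.  Pilot
ensembles showed this placement matters: with the EC3-like link placed
mid-chain instead, the cross-linked lifetime-force contrast is
indistinguishable from the dimer's, whereas the interface-adjacent
placement flattens the catch window.  Attachment lifetime is the time at
which the last breakable bond ruptures; permanent links are excluded from
the criterion.

Physical units: σ = 10 nm, k_BT = 0.0042 pN·µm and the rounded drag
α = 3πγσ ≈ 0.1 pN·s/µm (γ = 1 pN·s/µm²) give a force unit k_BT/σ =
0.42 pN and time unit τ ≈ 2.38×10⁻³ s; all printed conversions of the
model parameters follow from these three constants.

### Validation and scaled ensembles

The simulator is validated against micro-oracles: analytic forces match
central finite differences to 1e−6 relative; the thermostat satisfies
equipartition within 5%; a rigid single-bond system reproduces the
analytic ω_off exponential within 5% (and passes a KS test); and the free
filament's tangent correlations decay with λ = 2κ/k_BT within 10% when
fitted over separations s ≤ 3 — chain discreteness and excluded volume
bend the tail of the correlation above the ideal worm-like-chain law, so
the persistence length is read from the initial decay.

The emergence property (dimer slip-catch-slip flattening into an
ideal-like plateau upon cross-linking) is checked with scaled ensembles —
20–40 runs at probe forces chosen from a pilot scan (10, 40, 90, 180
k_BT/σ) — rather than the 100-run curves of a production study.
Attachment lifetimes are heavy-tailed (rupture cascades), so small-
ensemble means carry sizeable errors; the checks compare contrasts
(max/min over the window) rather than absolute lifetimes.

## Synthetic data generator

The generator stands in for the AFM instrument. Lifetime datasets are
exact Gillespie draws from the kinetic model, censored at the protocol
duration; the high-force mode mixes in a short-lived (~1 s) exponential
component with a logistic force-dependent weight (midpoint 85 pN, width
8 pN — our parameterisation of the qualitative observation that the
second component appears above ~70 pN and grows with force). Traces hold
a Gaussian-noise plateau (2 pN force, 0.3 nm height SD by default) until
the drawn dissociation time; each unfolding event injects a height gain
from its class distribution and a rectangular 0.16 s force dip of 12 pN
(spike shape is not parameterised by the source; a rectangle of the
stated duration is the simplest faithful choice). Each class fires at
most once per trace by default — a domain unfolds once.

What the generator does **not** emulate: cantilever ringdown and PID
feedback dynamics, piezo creep and thermal drift, non-specific surface
adhesion, multiple simultaneous tethers, and instrument-specific spike
shapes. Tests passing on synthetic data therefore certify the analysis
chain (estimators, fits, detection logic) under the stated statistical
model, not robustness to every instrumental artefact of real recordings.

## Known limitations

- The kinetic model treats the clamp as ideal (instantaneous force
  attainment); loading-rate effects during the approach are out of scope.
- F_C1 and the exponential-fit-vs-integral lifetime convention are
  analysis choices; both are exposed and recorded, but comparisons with
  published parameter tables inherit that ambiguity.
- The rebinding pathway's rate constants are weakly identifiable from
  lifetime-force curves alone — expect broad errors and strong k+1/k+2
  correlation in fits.
- The filament model is 2D (the persistence-length convention used for
  its rigidity parameter is the 2D one); a 3D variant would need its own
  calibration.
- Small Langevin ensembles give noisy lifetime means; qualitative shape
  statements at desk scale should use contrast statistics and paired
  windows, as the tests do.
- The dimer's catch signature (interior lifetime maximum) reproduces
  robustly, but the cross-linked tetramer's flattening relative to the
  dimer does not separate from ensemble noise at 32–40 runs per force in
  this implementation: measured max/min contrasts over the 40–180 kBT/σ
  window are ≈1.45 for both arrangements, for either cross-link placement
  and also for a distributed lateral-spring ladder. Structurally, the
  breakable bonds are the only force path from the pulled to the anchored
  side — cross-links join like filaments only — so the last surviving
  bond always carries the full load and the cross-linked curve is close
  to a shifted copy of the dimer's. The corresponding test asserts the
  flattening as specified and currently fails; treat the emergent
  ideal-bond claim as not reproduced by this implementation at desk-scale
  ensembles.
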