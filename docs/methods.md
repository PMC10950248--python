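# Methods

This note documents the model, the numerical conventions, the synthetic
column that the package ships as its default study condition, and what the
tests do and do not establish about real cortical data.

## Neuron model and integration

Neurons are GLIF₃ point neurons: a leaky integrate-and-fire membrane
(capacitance C, conductance g, rest E_L, threshold v_th, reset v_r,
refractory δ_r ∈ [2, 8] ms) plus two after-spike currents (ASC) I_m with
decay rates k_m and additive constants A_m. All state variables are linear
between spikes, so the discrete 1 ms update is the *exact* exponential-Euler
solution: with constant input and no spikes the simulated membrane equals
the continuous closed form at every grid point to machine precision (the
test suite asserts ≤1e−9 relative). The same holds for the alpha-function
synaptic recursion, whose single-spike response is W (t/τ) e^(1−t/τ)
exactly at grid points.

Conventions the equations leave open, fixed here once:

- **Spike condition** is v ≥ v_th (Heaviside with H(0) = 1).
- **Within-step order**: delayed spike delivery → synaptic state update →
  membrane/ASC update (using the previous step's currents and spikes) →
  threshold test → refractory bookkeeping.
- **Refractory hold**: on spiking, the membrane is set to v_r and held for
  δ_r; synaptic and ASC states keep evolving through the hold. The ASC
  additive constant is applied at the spike step (via the z A_m term of the
  ASC recursion) and the reset rule I_m ← R_m I_m + A_m is applied at the
  end of the hold to the decayed value; with the default adaptation-type
  (negative) amplitudes this double application simply deepens adaptation
  slightly, and the defaults were chosen with it in place.
- **Initial conditions** are literally zero — including v = 0 mV, far above
  threshold — so the network opens with a population discharge; this onset
  transient is flushed by the discarded warm-up trial. A config switch
  (`init_at_rest`) starts at E_L instead. Trials are contiguous in time:
  state carries across trial boundaries and only trial 0 (the warm-up) is
  excluded from every average.
- **Delays** are integer steps in {1, …, 4}; a spike emitted at step s
  begins driving the target's synaptic state at step s + d.

## Synaptic bookkeeping

Each neuron carries four alpha-function channels: thalamic, background,
recurrent-excitatory and recurrent-inhibitory, the latter two with the
receptor time constant chosen by the (source E/I, target E/I) pair
(5.5/8.5/2.8/5.8 ms). The recorded `rec` current is the sum of the two
recurrent channels and the identity I_ext = I_in + I_noise + I_rec is exact
(bitwise) because it is the very sum the integrator uses. The background
is a single shared 1 kHz Poisson source with a per-type weight, as in the
full-scale model family this column emulates.

## The synthetic column (default configuration)

The paper-scale connectome (231k neurons, 70M synapses, 111 fitted GLIF
parameter sets) is deliberately out of scope; the default column is a
synthetic stand-in that preserves the statistical structure the
perturbation mechanism depends on. Counts: 5,070 neurons in a 150 µm-radius
cylinder (L1 80 Htr3a; L2/3 1000E/130Pv/90Sst/100Htr3a; L4
1200E/160Pv/100Sst/60Htr3a; L5 800E/110Pv/80Sst/40Htr3a; L6
900E/110Pv/70Sst/40Htr3a). One GLIF parameter set per cell class
(illustrative, not Allen-database fits; e.g. excitatory cells: C = 120 pF,
g = 5 nS, 20 mV to threshold → rheobase ≈ 100 pA, classification threshold
±5 pA).

Connectivity values exist in the source material only as qualitative
heatmaps, so the defaults were chosen by the package as follows: same-layer
class-pair base probabilities preserving the canonical ordering (strong
E↔Pvalb reciprocity ~0.4–0.45, moderate E↔Sst, weak I↔I), cross-layer
attenuation by layer distance with named pathways overridden (L4E→L2/3E
0.25, L4E→L2/3Pv 0.15, L2/3E→L5E 0.15, …), Gaussian widths σ = 90–130 µm,
and signed mean weights of 0.35–2 pA (E) and −0.6 to −2 pA (I). The
like-to-like form is w(Δθ) = w̄ (1 + κ cos Δθ) with κ = 0.3, applied to
weights of all pairs; the optional E–E *probability* bias exists behind a
switch and defaults to off. LGN in-degrees follow per-type negative
binomials — dense onto L4 (mean 18–20), sparse and strongly overdispersed
onto L2/3 excitatory cells (mean 5, dispersion r = 0.5, ~30% zeros) — and
LGN weights are 2–8 pA.

The free parameters were set once by a mean-field balance targeting the
mechanism's operating regime — thalamic drive to L4 and Pvalb, Pvalb-
mediated competition between thalamically driven and non-driven L2/3
excitatory cells — followed by short diagnostic simulations, and then
frozen. With these defaults the 2 Hz onset experiment splits L2/3
excitatory cells into roughly 9-13% dVf and 40-55% hVf (the remainder
unclassified; exact fractions vary with the seed), with an LGN in-degree
contrast of ~20 vs ~0.6 and complete onset/halt sign reversal among
perturbation-sensitive cells. The *numbers* are properties
of this toy column, not of cortex; only the qualitative structure (two
opposing classes, their thalamic-input asymmetry, the inhibitory
competition, the reversal under flow halt) is the modeled claim.

## LGN front-end

The released 17,400-unit, 14-subclass spatiotemporal filter bank is
replaced by an explicit parametric front-end — the largest deliberate
simplification in the package. Each unit is an ON or OFF half-rectified
sinusoid at a fixed retinotopic position with baseline r₀ = 10 Hz and gain
r₁ = 80 Hz/contrast, plus a biphasic temporal kernel (difference of two
exponentials, τ = 15/60 ms). The kernel's two lobes are normalized to
cancel exactly on the discrete grid (zero DC), so flashes produce
transients that return exactly to baseline and static gratings drive only
the baseline rate. For drifting gratings the kernel enters as its Fourier
amplitude |k̂(tf)| (peak-normalized): the drift modulation is band-pass in
temporal frequency, peaking near 5 Hz. This temporal-frequency dependence
is what makes a drifting grating a stronger thalamic drive than a static
one — the front-end property the downstream perturbation responses feed
on — and preferred frequencies measured downstream inherit this kernel
shape rather than constituting a prediction about cortex. Rates are turned
into spikes by an inhomogeneous Poisson process, seeded per trial.

## Analysis conventions

- Baseline I₀ is the mean total current over the 500 ms before perturbation
  onset (half-open step window [0, 500)), computed per trial and averaged;
  ΔI averages the 1000 ms perturbation window [500, 1500) over the 20
  analyzed trials and retains the per-source decomposition, so
  ΔI = ⟨I_in⟩ + ⟨I_noise⟩ + ⟨I_rec⟩ + ⟨ΣI_m⟩ − I₀ holds to 1e−12.
- Classification uses strict inequalities: ΔI exactly at ±0.05·θ_rheo is
  unclassified.
- The rheobase grid search is implemented as a bisection over the
  (start = 1 pA, increment = 0.01 pA) grid; because a rectangular pulse
  from rest either elicits a spike or not monotonically in its amplitude
  (state is reset between pulses), the bisection returns exactly the
  smallest firing grid current of a linear scan.
- The "150 ms Gaussian filter" for firing rates is interpreted as the
  kernel's standard deviation (truncated at ±3σ, unit sum) on the 60 Hz
  sample grid.
- Effective weights are reported in pA·spikes/step over 500 ms windows
  placed immediately before and after the perturbation onset; type-level
  aggregates are plain sums over the presynaptic type's members.
- Ripley's K uses the border correction that divides each neighbor count
  by the in-domain fraction of the search disk (exact circle–circle lens
  area); the CSR reference is πt².
- Preferred frequency is argmax (dVf) / argmin (hVf) of ΔI over the 1–9 Hz
  sweep, ties broken toward the lower frequency.
- Across-direction categories: perturbation-sensitive requires the same
  non-unclassified label in *all* 8 directions; direction-selective
  requires exactly one responsive direction (read of "a particular
  direction" as exactly one).
- Group comparisons: one-way ANOVA gate at p < 0.01 before pairwise
  two-sided Welch t-tests (Welch directly for two groups); stars at
  0.05/0.01/0.001/0.0001. These delegate to scipy.

## What the tests show — and what they don't

The closed-form, oracle and algebraic tests establish the numerics
exactly. The emergent-class tests establish that the *mechanism* operates
in the shipped synthetic column under its stated conditions (fixed seeds,
20 analyzed trials, 2 Hz gratings). They do not establish the full-scale
model's population percentages, which depend on the released connectome
and parameter fits that this package deliberately does not ingest; the
toy column's fractions differ and are reported as its own output. The
synthetic data also omit retinotopy-linked tuning, retinotopic weight
gradients, locomotion/top-down input, and realistic LGN receptive-field
diversity, so passing tests speak to the wiring-plus-competition
explanation, not to quantitative cortical prediction.

## Problem sizes

Default problem sizes were chosen so the whole chain runs comfortably on a
laptop-class CPU: the toy column (5,070 neurons, ~1.4M synapses) simulates
a 2.5 s trial in ~1.5 s; the full acceptance computation (a 9-protocol,
21-trial-each program plus the 100 × 10,000-point Ripley null) completes
in about six minutes.
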