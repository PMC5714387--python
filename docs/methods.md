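# Methods

## The inverse problem

The pre-motor locomotory circuit of *C. elegans* comprises five command
interneuron classes (AVA, AVB, AVD, AVE, PVC), the sensory neuron DVA, the
polysensory neuron ASH, and the A- and B-type motor neurons that drive
backward and forward undulation, modeled as two averaged pools E_b and E_f.
The anatomical connectome gives contact counts per directed connection but
not the sign of the postsynaptic effect.  This package infers those signs
(the polarity bits eps_ij, 1 excitatory / 0 inhibitory), the input-polarity
vector sigma, and six uncertain physiological parameters, by requiring that
the circuit's stationary output reproduce the fraction of time the worm
spends moving forward across a panel of 18 circuit variants (wild type plus
17 ablation combinations).

## Circuit model

Each interneuron carries graded (non-spiking) voltage dynamics

    C dV_i/dt = -g_L (V_i - V_L) - g_Ca m_i^2 (V_i - V_Ca)
                - g_KCa [Ca]_i/(K_D + [Ca]_i) (V_i - V_K)
                - sum_j a_i a_j g_ij (V_i - V_j)
                - sum_j a_j w_ij H(V_j) [V_i - (1 - eps_ij) V_Cl] + X_i,

with gating m(V) = 1/(1 + exp(-(V+20)/9)), synaptic activation
H(V) = 1/(1 + exp(-gamma (V - theta))), gap conductances g_ij = N^e_ij q_e,
synaptic strengths w_ij = N^s_ij q_s, and ablation indices a_i in {0, 1}.
Excitatory synapses pull toward 0 mV, inhibitory ones toward V_Cl = -50 mV.
Motor pools carry only leak, gap and synaptic currents; calcium follows

    d[Ca]_i/dt = -[Ca]_i / tau_Ca - 2 g_Ca m_i^2 (V_i - V_Ca) / (d F).

ASH is held at the constant operating point V_ash = c_ash * theta_ash and
acts through its outgoing connections and through the input modulation
X_i = X_o sigma_i [1 + a_ash f_ash H_ash(V_ash)].  The wild-type state
vector has 14 components: six interneuron voltages, six calcium
concentrations, and E_f, E_b.

Synaptic activation constants are chosen by the *presynaptic* neuron:
ASH-presynaptic terms use (theta_ash, gamma_ash) = (-90 mV, 0.03 /mV),
all others (including inputs to the motor pools) use (-40 mV, 0.08 /mV).

### Units and the calcium conversion constant

All quantities are in mV, ms, uA/cm^2, mS/cm^2, uF/cm^2 and uM.  The influx
term 2 g_Ca m^2 |V - V_Ca| / (d F) has units

    (mS/cm^2 * mV) / (cm * C/mol) = 1e-6 mol / (s * cm^3) = 1 uM/ms,

so with the dendrite diameter converted to cm (d = 0.5 um = 0.5e-4 cm) and
F = 96485 C/mol the conversion constant `CA_UNIT_FACTOR` is exactly 1.0.
With the default conductances this puts stationary calcium near 25 uM at a
typical operating voltage of -30 mV, inside the physiologically expected
1-100 uM window.

### Parameters

Optimized (search ranges in parentheses): q_s (0-0.07 mS/cm^2),
q_e (0-0.07 mS/cm^2), X_o (0-4 uA/cm^2), c_ash (0-2), f_ash (-1-1),
eta (1-10 mV).  Defaults are the best-fit values q_s = 0.039, q_e = 0.042,
X_o = 3.5, c_ash = 0.5, f_ash = -0.8, eta = 2.0.
Fixed: g_L = 0.0067 mS/cm^2, V_L = -60 mV, V_Ca = 120 mV, V_K = -90 mV,
V_Cl = -50 mV, g_Ca = 0.043, g_KCa = 0.057 mS/cm^2, K_D = 30 uM,
tau_Ca = 150 ms, d = 0.5 um, C = 1 uF/cm^2.

## Behavior model

Three locomotory states (forward, backward, stop) form a continuous-time
Markov chain with no direct forward/backward transitions and Arrhenius-type
rates W = W_o exp[+-(E_f - E_b -+ Delta)/(4 eta)].  The stationary
distribution is closed-form, and the forward-time ratio

    R = T_f/(T_f + T_b) = 1/(1 + exp[(E_b - E_f)/eta])

is independent of the stop threshold Delta and the basal rate W_o; those two
enter only when stop-state occupancies or trajectories are requested
(defaults Delta = 5 mV, W_o = 1 Hz).  Exponentials are evaluated through
log-sum-exp so extreme drives cannot overflow.

## Goal function

A candidate configuration is scored by the standardized Euclidean distance

    SED = sqrt( sum_i [(R_th_i - R_exp_i)/SD_exp_i]^2 )

over the ablation panel.  The square root is part of the definition: a panel
of 18 variants each off by exactly one standard deviation scores
sqrt(18) = 4.24.  Variants whose steady-state solve fails to converge
receive the penalty residual 10 * max(1, max |converged residuals|) and are
flagged; the search stays well-defined without mistaking a failed solve for
a prediction.

## Steady-state computation

Two solvers are provided.

* `dopri` — windowed integration with the Dormand-Prince 5(4) pair
  (rtol 1e-8), declaring stationarity when the state-scaled residual drops
  below 1e-8 or the state moves less than 1e-6 over a 2 s window.
* `hybrid` (default) — pseudo-transient Newton on the voltage-reduced
  system: calcium is slaved to its closed form
  [Ca]_ss(V) = -2 tau_Ca g_Ca m^2 (V - V_Ca)/(dF), and the remaining
  voltage equations are solved by damped Newton whose continuation
  parameter starts at an implicit-Euler step of 5 ms and grows
  geometrically, so early iterations follow the flow from the canonical
  initial condition (V = V_L, calcium at its closed form).  The converged
  root is accepted only if the full 14-dimensional Jacobian restricted to
  non-ablated components has strictly negative real eigenvalue parts.
  Unstable or failed roots trigger a fallback that follows the true flow
  with an unconditionally stable exponential-Euler relaxation (10 ms
  steps, 2 s windows) and polishes each window's endpoint with plain
  Newton, up to a 10 s horizon.

The hybrid path exists because ablations can leave a neuron without
synaptic anchoring; with a strong constant input such a neuron sits on a
bistable branch whose intermediate fixed point is an unstable spiral
(e.g. DVA in the AVB/PVC double ablation settles in a depolarized
calcium-plateau state).  Newton alone would report the unstable root; the
relax-and-polish fallback lands on the attractor the flow actually selects.
Tests cross-check the two solvers on wild-type and ablated circuits.
Genuinely oscillatory configurations never become stationary; they exhaust
the integration budget, are flagged, and receive the SED penalty.

Initial condition and tie-breaks: V_i = V_L for every neuron and both
pools, calcium at its closed form; bistability is handled by following the
flow from this state, never by picking the lower-energy root.

## Optimizer

A genome is a flat bit vector: 16 bits per optimized continuous parameter
(quantization step = range/65535, far below the sensitivity widths of the
SED profiles), one bit per input receiver for sigma, one bit per free
connection for eps.  Islands hold pools of 35 genomes and evolve
independently for 30 inner loops; each loop proposes, for every member, a
differential mutation built from three distinct donors — DE/rand/1 with
factor 0.8 on decoded continuous values, and a per-bit mix (probability
0.5) from a XOR (b AND c) on discrete slices — crosses 20% of the entries
into the target, and keeps the better of target and trial (greedy elitism;
ties keep the incumbent).  After each inner phase the global best genome
replaces every island's worst member (a ring topology is available).  The
run stops when the global best improves by less than 1e-3 across two
consecutive migrations.  Defaults use 4 islands at desk scale; the island
count is configuration, and results are reproducible from the seed and
independent of the parallel worker count because each island owns a
spawned random stream.

## Search-space reduction

Connections with mean contact count <= 0.75 are removed from the dynamics
entirely, shrinking the polarity space from 2^38 to 2^26 (a 4096-fold
reduction); the cut-off comparison is inclusive.  The free list is ordered
by decreasing weight so restricted studies ("the n strongest connections")
are prefixes; restricted connections stay in the dynamics pinned at
inhibitory polarity.

## Synthetic data

The packaged connectome is a synthetic reconstruction: the counting
structure is exact (38 optimizable connections, 12 at or below the 0.75
cut-off, a unique strongest connection AVA->E_b above 15.75, E_b->PVC the
only fixed excitatory link), the individual contact counts are plausible
values consistent with the relative strengths the analyses report
(AVD->AVA second strongest; AVD->E_b and AVE->E_b strong; AVB's synapses
onto motor neurons weak while its gap junction to E_f is strong).  Gap
junction counts are placeholders with the documented ordering (AVA-E_b
strongest, AVB-E_f and AVA-PVC strong) and are swappable through the JSON
schema.  The 18-variant ablation panel is likewise a documented
reconstruction (all singles plus multi-ablations including ASH alone and
ASH with AVA/AVB) and can be overridden with a TSV file.

Behavioral tables are generated from a planted truth: the "optimal"
preset uses the best-fit parameters, all free connections inhibitory and
sigma_AVA = -1 (all other receivers +1); the "random" preset draws
uniformly from the search ranges.  Observed ratios are
clip(R_th + N(0, noise_sd), [0, 1]) with recorded SD = max(noise_sd, 0.01);
the SD floor keeps SED finite for noise-free panels, and clipping slightly
biases variants whose true R sits near 0 or 1.  What passing recovery tests
show is that the pipeline identifies planted signs under its own generative
model at realistic noise; they cannot show robustness to model misspecification
(real behavioral data contain history effects, measurement structure and
inter-individual variability that this generator does not emulate).

## Problem sizes used in the shipped studies

The recovery study fixes the continuous parameters at the planted truth and
searches the 8 strongest polarity bits plus the 6 input bits (16384
configurations) with 4 islands x pool 35 x 30 inner loops, ten seeds,
verified against exhaustive enumeration of the 2^8 polarity patterns; this
size cleanly separates signal (noise 0.02 on R) while keeping the study
quick on a workstation.  Repeated configurations are served from a cache
keyed by the genome bits; caching changes run time only, never results.

## Known limitations

* Measured behavioral tables are not shipped with the package;
  headline fitted values from the real ablation experiments are not reproducible here
  and are out of scope.  All quantitative tests run against planted-truth
  synthetic panels.
* Gap-junction polarity is not modeled (electrical coupling is sign-free),
  and only one stop state is used.
* Voltage noise eta enters the behavior map only; the circuit ODEs are
  deterministic.
* Steady-state analysis ignores limit cycles by design: oscillatory
  variants are reported as non-converged rather than averaged.
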