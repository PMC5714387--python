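# synpolarity

Inference of synaptic connection polarities in the *C. elegans* pre-motor
locomotory circuit from behavioral ablation data.

## The problem

The anatomical connectome of the worm's locomotion command circuit — five
pre-motor interneuron classes (AVA, AVB, AVD, AVE, PVC), the sensory
neurons DVA and ASH, and the A/B motor neuron pools (E_b, E_f) — gives the
number of synaptic contacts per directed connection but not their sign.
Because the same neuron can excite one target and inhibit another, the sign
must be assigned per *connection*, and with 38 optimizable connections the
space of sign patterns is 2^38 ≈ 2.7·10¹¹.

`synpolarity` solves this inverse problem by reverse engineering: a
conductance-based model of the circuit (graded potentials, Ca²⁺ and
Ca²⁺-activated K⁺ currents, gap junctions, signed chemical synapses) is
driven to its stationary state for each of 18 circuit variants (wild type +
17 ablation combinations); the motor-pool voltage difference sets the
forward-time ratio

    R = T_f / (T_f + T_b) = 1 / (1 + exp[(E_b − E_f)/η])

through a three-state Markov model of locomotion; and candidate sign
patterns are scored with the standardized Euclidean distance

    SED = sqrt( Σ_i [(R_th,i − R_exp,i)/SD_exp,i]² )

against the behavioral table.  An island genetic algorithm over a binary
genome (16 bits per continuous parameter, one bit per input sign, one bit
per connection polarity) minimizes SED.  Sub-threshold connections (mean
contact count ≤ 0.75; 12 of the 38) are removed from the dynamics, reducing
the search space 4096-fold.

The measured behavioral table from the original ablation experiments is not
redistributable, so the package ships a first-class synthetic-data module:
panels are generated from a planted ground truth, and the test suite
demonstrates exact recovery of the planted polarities and input pattern.
See `docs/methods.md` for the full model description.

## Worked example

```python
import synpolarity as sp
from synpolarity.model import CircuitPolarityModel
from synpolarity.optimizer import GAConfig

# planted ground truth: all free connections inhibitory, input pattern
# inhibiting AVA and exciting the other receivers, 8 strongest connections free
truth = sp.make_truth("optimal", seed=1, n_free=8)
data = sp.make_behavioral_data(truth, noise_sd=0.02, seed=1)

model = CircuitPolarityModel(
    data, connectome=truth.connectome, n_free=8,
    base_params=truth.params, optimize_fields=(), optimize_sigma=True,
)
result = model.fit(GAConfig(islands=4, pool_size=35, inner_loops=30, seed=42))
print(result.summary())
```

prints (abridged):

```
Circuit polarity fit (island genetic algorithm)
=======================================================
SED at optimum                2.4343
variants                          18
free connections                   8
migrations / evaluations       3 / 12740

Input pattern sigma
-------------------------------------------------------
  AVA      -1
  AVB      +1
  AVD      +1
  AVE      +1
  PVC      +1
  DVA      +1

Synaptic polarities (free connections)
-------------------------------------------------------
   AVA -> E_b  (w=17.00)  inhibitory
   AVD -> AVA  (w=12.20)  inhibitory
   AVE -> E_b  (w= 7.60)  inhibitory
   ...
   PVC -> E_f  (w= 4.00)  inhibitory

Per-variant fit
-------------------------------------------------------
  wild_type      R_exp=0.817 R_th=0.810 resid=-0.35
  AVA-           R_exp=0.965 R_th=0.948 resid=-0.82
  AVB-           R_exp=0.220 R_th=0.213 resid=-0.33
  ...
  PVC-DVA-       R_exp=0.975 R_th=0.981 resid=+0.29
```

The fitted SED equals the planted configuration's own score (the residual
noise floor of the 0.02-noise panel), every free connection is recovered as
inhibitory, and the input pattern is recovered as σ_AVA = −1 with all other
receivers excited.

Post-fit analyses hang off the results object:

```python
result.flip_scan()           # SED after each single polarity flip
result.input_pattern_scan()  # exhaustive 2^6 = 64 input patterns
result.parameter_sweep("X_o")
result.ablation_report()     # stationary V, [Ca] and current decomposition
```

A thin CLI mirrors the library: `synpolarity synth | fit | flip-scan |
input-scan | cutoff-scan | sweep | ablate-report`.

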