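# assocmem

Associative memory storage in noisy, sign- and norm-constrained networks
of binary neurons.

## The problem

Local cortical circuits are thought to store associative memories in
their recurrent connectivity, but every step of signal transmission is
noisy: neurons spike unreliably, synaptic transmission is quantal and
variable, and thresholds fluctuate. `assocmem` is a research library for
asking how much memory such a circuit can store, how reliably the stored
sequences can be replayed, and what the resulting connectivity and
dynamics look like — for computational neuroscientists who want a tested,
scriptable implementation of the full storage-and-retrieval pipeline.

The model: a recurrent network of `N` McCulloch–Pitts neurons (`N_inh`
inhibitory) learns a sequence of random binary states
`X¹ → X² → … → X^(m+1)` with firing probability `f`. Each neuron adjusts
its input weights `J_ij` under Dale sign constraints (`J_ij g_j ≥ 0`) and
a fixed l1-norm (`(1/N) Σ_j |J_ij| = w`), while learning is corrupted by
balanced spiking errors of rate `r` (a 1 flips with probability `r/2f`, a
0 with `r/2(1−f)`), synaptic noise with `var(J*) = (hβ_syn/N)|J|`, and
Gaussian threshold noise with `var(h*) = h²β_int²/N`. In the large-N
limit the success condition per association is a Gaussian margin
inequality,

    (2y−1) I ≥ (D⁻y + D⁺(1−y)) σ,   D∓ = √2 erfinv(1 − r_out/f_out), …

and the noise sources enter the capacity only through the postsynaptic
noise strength `β = sqrt(β_int² + w̃ β_syn f)` with `w̃ = Nw/h`.

Three routes solve the storage problem, and the package implements all
of them against one shared margin module:

* **replica theory** (`solve_homogeneous`, `solve_heterogeneous`) — the
  critical capacity `α_c`, connection probabilities and the
  truncated-Gaussian weight distribution in the `N → ∞` limit;
* **convex optimization** (`load_neuron`, `load_network`,
  `estimate_capacity`) — finite-N loading by slack-sum minimization
  (trust-region sequential LP on an exactly convex program);
* **online learning** (`train_neuron`, `perceptron_capacity`) — a
  biologically plausible four-step perceptron rule with sign and norm
  projections at every mismatch-triggered update.

On top of these, `simulate` replays loaded sequences under retrieval
noise and measures spontaneous dynamics (ISI CV, spike correlations,
E/I balance), and `information` converts retrieval statistics into
retrieved bits per playout.

## Worked example

`examples/01_capacity_theory.py` solves the saddle-point system at the
default network point (`f = 0.2`, `r = 0.02`, `w̃ = 20`, 20% inhibitory):

```
  beta   alpha_c   P_inh   P_exc  CV_inh  CV_exc
     0    0.4448   0.675   0.393   0.697   0.786
    10    0.2535   0.489   0.264   0.759   0.820
    20    0.1334   0.314   0.160   0.807   0.849
    30    0.0824   0.217   0.108   0.833   0.866
    50    0.0416   0.124   0.060   0.860   0.885
```

Each row is one learning-noise strength `β`. `alpha_c` is the critical
capacity (storable associations per input): it drops as noise during
learning grows. `P_inh`/`P_exc` are the fractions of inhibitory and
excitatory inputs with non-zero weight at capacity — inhibitory
connectivity is always denser, as observed in cortex — and the CV columns
give the coefficient of variation of the non-zero weight magnitudes.
The other examples load finite networks and measure capacity
(`02`), demonstrate the capacity–reliability trade-off (`03`), train a
neuron online (`04`), quantify spontaneous balanced dynamics (`05`) and
account for retrieved information (`06`).

A thin CLI mirrors the library for batch runs
(`assocmem replica-sweep|capacity|load|retrieve|dynamics|info-map|
perceptron-train`, each driven by a YAML config and writing tidy CSV
artifacts plus a manifest).

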