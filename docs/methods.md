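# Methods

## The model

`assocmem` studies associative sequence storage in a recurrent network of
`N` McCulloch–Pitts neurons, `N_inh` of them inhibitory. The network learns
a sequence of binary states `X^1 -> X^2 -> ... -> X^(m+1)` whose entries
are independent Bernoulli(f) draws; `m/N` is the memory load. Neuron `i`
must map the network state at one step to its own target bit at the next
step by adjusting its input weights `J_ij` under two constraints that hold
throughout learning:

* **Dale sign constraints** — `J_ij g_j >= 0`, with `g_j = ±1` the fixed
  sign of presynaptic neuron `j`;
* **l1-norm homeostasis** — `(1/N) Σ_j |J_ij| = w_i`, a fixed average
  absolute input weight.

Learning and retrieval are corrupted by three noise sources:

* **spiking errors** — balanced bit flips of rate `r`: a 1 becomes 0 with
  probability `r/(2f)` and a 0 becomes 1 with probability `r/(2(1-f))`, so
  the firing probability is preserved. Stability of the theory requires
  `r < 2f(1-f)`, enforced at construction.
* **synaptic noise** — each weight realization `J*` has mean `J` and
  variance `(h β_syn / N) |J|` (quantal transmission: variance grows with
  the mean). The distribution family is Gaussian; only the first two
  moments enter the large-N theory, and sign constraints bind the mean
  weights, not individual realizations.
* **intrinsic noise** — the threshold `h*` is Gaussian with mean `h` and
  variance `h² β_int² / N`, absorbing all non-synaptic PSP variability.

A neuron has learned an association successfully if its probabilities of
spike failures and erroneous spikes stay below `r/(2f)` and `r/(2(1-f))`.
In the large-N limit the PSP margin is Gaussian with closed-form mean `I`
and SD `σ`, and success becomes the margin inequality
`(2y-1) I >= (D⁻ y + D⁺(1-y)) σ` with `D∓ = √2 erfinv(1 - r_out/f_out)`
and `√2 erfinv(1 - r_out/(1-f_out))`. All solvers in the package share this
single inequality (module `margin`).

Internally all computations use `h = 1` and scaled weights
`J~ = (N/h) J`; margin decisions are invariant to this convention (tested).

## Replica solution at critical capacity

At the critical load the solution region of the margin inequalities
shrinks to a point and the replica-symmetric saddle-point conditions close
into a small nonlinear system. Two parametrizations are implemented:

* **heterogeneous** (`solve_heterogeneous`): six latents
  `(u₊, u₋, x, η, y, z)` with per-input sums over coefficients
  `B_j = r_j (1 - r_j / (4 f_j (1-f_j)))` and
  `C_j = f_j (1-f_j)(1 - r_j/(2 f_j (1-f_j)))²`;
* **homogeneous two-class** (`solve_homogeneous`): five unknowns
  `(u₊, u₋, v₊, v₋, x)` in which both noise strengths collapse into the
  postsynaptic noise strength `β = sqrt(β_int² + w~ β_syn f)` and the
  spiking errors into `ξ = B K²/(4C)` and `ζ = K/(2 w~ √C)`, with
  `K = D⁺ + D⁻`.

The solution yields the critical capacity `α_c`, per-input connection
probabilities `P_con = E(v)` and a truncated-Gaussian density of non-zero
scaled weights with SD `σ w~` (functions `E(x) = (1+erf x)/2`,
`F(x) = e^{-x²}/√π + x(1+erf x)`, `D(x) = x F + E`, evaluated via `erfcx`
on the negative branch for accuracy to `|x| ≈ 30` and beyond).

Numerics: the output-side split `u₊/u₋` is eliminated analytically by a
1-D Brent solve nested inside a damped-Newton (`scipy.optimize.root`,
`hybr`) outer iteration over the remaining unknowns, with heuristic
multi-starts and a mirror-branch restart (`u₊+u₋ < 0` is unphysical).
Residuals are scaled per equation and accepted below `1e-11`
(convergence errors carry the best residual). Internal cross-checks,
all exercised in the test suite:

* the l1-norm and excitation/inhibition balance identities of the weight
  distribution hold analytically (`⟨|J~|⟩ = (w~/2P_con)(N/N_class)(1 ∓
  1/(w~ f))`);
* the solution depends on `(β_int, β_syn)` only through `β`;
* at `r_in = 0` the system reduces, with every `K` factor cancelling, to
  the classical robustness-parameter (κ) model at `ρ = β ζ`
  (`solve_kappa` implements that reduced system as a separate codepath);
* at `f = 0.5` and vanishing noise `α_c -> 1`, the known capacity of
  sign-constrained perceptrons, and the noise-free finite-N LP capacity
  crosses 0.5 exactly at `α_c`;
* `r_out = 0` is excluded (the margin multipliers diverge); callers
  wanting "no tolerated output errors" use the κ-model mapping.

## Finite-N loading (optimizer)

For finite `N` each neuron minimizes the sum of per-association slack
variables subject to the margin inequalities, the norm equality and the
sign constraints. In magnitude variables `q_j = g_j J~_j >= 0` the noise
SD is a convex (norm-like) function of `q`, so the program is convex and
any KKT point is globally optimal. It is solved by trust-region
sequential linear programming: the exact piecewise-linear model of the
slack sum (first-order expansion of `σ`) is minimized with HiGHS inside
an adaptive box, steps are accepted on sufficient decrease of the true
slack sum, and the iteration stops at feasibility (slack below
`1e-6 · m · w~`), first-order stationarity, or trust-region collapse.
Sign constraints hold exactly by construction; the norm equality is
restored to machine precision after each accepted step. A weight counts
as an absent connection below `1e-8 · w~` (LP basic solutions produce
exact zeros).

Two solution-selection modes exist because the optimum is typically a
face, not a point, below the critical load: the default LP **vertex**
(at most `m+1` non-zero weights — the sparsest extreme solution), and a
**centroid** (`centroid_solution`) that averages basic solutions of the
optimal face under random auxiliary objectives; every convex combination
of minimizers is again a minimizer, and the centroid approximates the
replica-typical weight vector. Connectivity statistics use the centroid;
feasibility and capacity are selection-independent.

Capacity protocol: geometric bracketing of the 0.5 success-probability
crossing, bisection to Δm = 1 with a fixed repetition count per load
(default 20), then a binomial-MLE logistic fit over all evaluated loads;
the bootstrap CI resamples per-load binomial counts and refits.

## Online perceptron rule

On each presentation the neuron computes its noisy output
`y* = θ(Σ J*_j X*_j - h*)` with freshly drawn input flips, synaptic and
intrinsic noise; a mismatch with the noise-free target triggers the
four-step update (perceptron step `γ (h/N)(2y-1) X*_j` with `γ = 0.1`,
sign projection, single-pass l1-norm restoration, second sign
projection). The second projection can leave a small norm residual; it is
tracked per epoch and vanishes as weights equilibrate. Associations are
presented in sequence order; one pass is an epoch. After each epoch the
**deterministic Gaussian feasibility** of the current mean weights is
evaluated and training stops when it holds; a Monte-Carlo stopping
alternative (`stopping="mc"`, empirical error rates within the tolerated
bounds over 400 draws) is available but is in practice *stricter* near
the boundary because sampling noise rejects marginal solutions. Training
is a compiled (numba) kernel; spiking errors are sampled by geometric
skipping over precomputed active/silent index lists, which is exact and
removes the per-input RNG cost. Initial weights are uniform at the norm
bound (`q_j = w~`), the simplest point satisfying both constraints.

## Network simulation

Retrieval starts at the first loaded state (error-free by construction)
and iterates the one-step map under retrieval noise `β_retr`; no
additional input flips are injected (`r_retr = 0` by default) — only the
network's own output errors propagate. The per-step error fraction
against the target sequence is bimodal for large networks: it either
fluctuates near the learned rate `r` or diverges to `2f(1-f)`, the
expected distance between random states of rate `f`. A trial is complete
if the fraction never crosses the midpoint `(r + 2f(1-f))/2`; the
retrieved length is the number of steps before the first crossing. The
midpoint is the maximally insensitive threshold placement.

`β_retr` is shorthand for a purely intrinsic decomposition
(`β_int = β_retr`, `β_syn = 0`); an explicit pair can be passed instead.
In the large-N theory only the combination matters; at finite N the
decomposition has a mild effect, and the intrinsic-only default keeps
simulation cost at `O(N)` noise draws per step.

Spontaneous runs start from a random Bernoulli(f₀ = 0.2) state and run
for T = 1000 steps by default; the first 100 steps are discarded as
transient (configurable). Statistics: per-neuron ISI CVs (neurons with
at least two ISIs; sample SD), mean zero-lag Pearson correlation over
neuron pairs with non-degenerate trains, and the E/I balance index —
the positive magnitude of the (negative) correlation between each
neuron's summed excitatory input and its summed signed inhibitory input.

## Information accounting

Each retrieved association carries
`I = H(X^{μ+1}) - H(X^{μ+1}|X^μ)` bits; for homogeneous networks both
entropies are closed-form binary-entropy expressions in `f` and the flip
rates (base-2 logarithms). Expected information per playout is reported
both counting complete retrievals only (`retrieval probability × m I`)
and crediting partial retrievals by length (`mean length fraction × m I`);
the former never exceeds the latter. SEs propagate the Monte-Carlo
uncertainty of the retrieval statistics by the delta method (linear
scaling with `m I`).

## Default parameter point

The package default — `f = 0.2`, `r_learn = 0.02`, `β_learn = 20`
(as `β_int = 20`, `β_syn = 0`), `w~ = N w / h = 20`, `N_inh/N = 0.2`,
`h = 1` — is a biologically plausible setting: learning noise in the
20–50 range and spiking error probability below 0.06 are where the
model's connectivity and dynamics statistics simultaneously match
cortical measurements, and at this point the finite-size capacity
geometry (N = 800 within ~10% of `α_c`, monotone in N) matches the
displayed behaviour of the model. At this point `α_c ≈ 0.133`,
`P_con ≈ 0.31` (inhibitory) and `0.16` (excitatory).

## Problem sizes used in tests and the acceptance script

Headline results in the paper-scale protocol average hundreds of networks
with up to thousands of trials; the shipped tests and
`scripts/acceptance.py` use scaled-down sizes chosen to keep a full run
on one CPU within tens of minutes: capacity estimates at `N = 200` with
20 sequence draws per load point, a six-point `β_learn` sweep with one
loaded network and 200 retrievals per point, finite-size checks at
`N = 200/400/800` with 8–20 draws, and Monte-Carlo oracles at `1e5`
draws. The perceptron epoch cap in these runs is `1e5` (default `1e6` in
the library, as in the full-scale protocol).

## Known limitations

* The perceptron capacity at a `1e5`-epoch cap is an underestimate of its
  converged value: the measured optimizer-vs-perceptron capacity gap at
  `N = 200` is ~32% at `1e5` epochs and ~28% at `3e5`, still above the
  15–18% reported for fully converged runs; only the lower bound of that
  range is checked at reduced budgets.
* Finite-size capacity corrections at the default noise point are larger
  than sometimes assumed: the measured `N = 800` capacity is ~0.81 of
  `α_c` (deficit ≈ `β/√N`); at low noise the `N = 400` capacity already
  reaches ~0.99 of `α_c`. The corresponding 10%-at-`N=800` acceptance
  check fails honestly at the default point.
* Finite-size corrections to the connectivity statistics scale like
  `β/√N`: at the default noise point the empirical excitatory connection
  probability at `N ≤ 800` remains below the replica value (the
  inhibitory one converges by `N = 800`), while at low noise (`β = 2`)
  both classes match within sampling error at `N = 400`. The
  corresponding acceptance check is expected to fail at tractable sizes
  at the default point.
* No replica-symmetry-breaking analysis; the sub-critical solution-volume
  system is not implemented (only the critical-capacity limit).
* No spatial structure, conduction delays, or continuous-time dynamics;
  synthetic sequences are i.i.d. Bernoulli, so temporally correlated or
  structured memories are untested territory.
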