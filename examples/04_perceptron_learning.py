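"""Online learning with the four-step noisy perceptron rule.

Trains a single neuron (N = 100 inputs) on a short associative sequence.
Each mismatch between the noisy output and the target triggers a
perceptron step followed by sign and l1-norm projections.  The printed
trace shows the Gaussian output-error probability falling toward the
tolerated spiking-error rate r; training stops once every association
satisfies the deterministic feasibility criterion.
"""

import numpy as np

from assocmem import AssociationSet, NetworkSpec, generate_sequence, train_neuron

N, BETA, R = 100, 10.0, 0.02
spec = NetworkSpec.homogeneous_network(
    N, frac_inh=0.2, f=0.2, r=R, beta_int=BETA, w=20.0 / N
)
seq = generate_sequence(spec, m=6, seed=11)
assoc = AssociationSet.from_sequence(seq, 0)
state = train_neuron(
    assoc,
    f=spec.f, r=spec.r, g=spec.g.astype(float),
    beta_syn=0.0, beta_int=BETA, w_tilde=20.0, f_out=0.2, r_out=R,
    gamma=0.1, max_epochs=50_000, seed=3,
)

print(f"converged: {state.converged} after {state.epoch} epochs")
idx = np.unique(np.geomspace(1, max(state.epoch, 2), 8).astype(int)) - 1
for i in idx:
    print(f"epoch {i + 1:6d}: output-error probability {state.error_trace[i]:.4f}")
print(f"target spiking-error rate r = {R}")
print(
    f"constraints after training: mean|J~| = {np.abs(state.weights).mean():.4f}"
    f" (target 20), sign violations: {int((state.weights * spec.g < 0).sum())}"
)
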