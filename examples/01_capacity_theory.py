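"""Critical capacity of a noisy neuron from the replica solution.

Solves the infinite-N saddle-point system at the default network point
(f = 0.2, w~ = 20, 20% inhibitory inputs) for a few postsynaptic noise
strengths and prints the critical capacity alpha_c together with the
inhibitory/excitatory connection probabilities of the critical solution.
alpha_c is the number of storable associations per input; it shrinks as
noise during learning grows, while connectivity gets sparser with larger
weights (the l1-norm is fixed).
"""

from assocmem import solve_homogeneous, weight_distribution

F, R, W_TILDE, FRAC_INH = 0.2, 0.02, 20.0, 0.2

print(f"{'beta':>6} {'alpha_c':>9} {'P_inh':>7} {'P_exc':>7} {'CV_inh':>7} {'CV_exc':>7}")
for beta in (0.0, 10.0, 20.0, 30.0, 50.0):
    sol = solve_homogeneous(F, R, F, R, beta, W_TILDE, FRAC_INH)
    wd = weight_distribution(sol)
    print(
        f"{beta:6.0f} {sol.alpha_c:9.4f} {sol.P_con_inh:7.3f} {sol.P_con_exc:7.3f}"
        f" {wd['inh']['cv']:7.3f} {wd['exc']['cv']:7.3f}"
    )
print(
    "\nEach row: more noise during learning (larger beta) lowers the critical"
    "\ncapacity and the connection probabilities; inhibitory inputs always"
    "\nconnect more densely than excitatory ones, as in cortical circuits."
)
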