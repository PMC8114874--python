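"""The capacity-reliability trade-off of loaded memory sequences.

Loads small networks to a fixed fraction of their capacity at several
learning noise strengths beta_learn, then replays the stored sequence
under retrieval noise beta_retr = 10.  Memories stored with more noise
are retrieved more reliably - but such networks hold fewer associations.
"""

from assocmem import (
    NetworkSpec,
    generate_sequence,
    load_network,
    retrieval_statistics,
    solve_homogeneous,
)

N, R, BETA_RETR = 100, 0.02, 10.0

print(f"{'beta_learn':>10} {'m':>4} {'P(retrieval)':>13} {'mean length frac':>17}")
for beta_learn in (5.0, 10.0, 15.0, 20.0):
    spec = NetworkSpec.homogeneous_network(
        N, frac_inh=0.2, f=0.2, r=R, beta_int=beta_learn, w=20.0 / N, seed=4
    )
    alpha_c = solve_homogeneous(0.2, R, 0.2, R, beta_learn, 20.0, 0.2).alpha_c
    m = max(int(round(0.55 * alpha_c * N)), 2)
    seq = generate_sequence(spec, m, seed=4)
    W = load_network(seq, spec)
    stats = retrieval_statistics(W, seq, spec, beta_retr=BETA_RETR, trials=100, seed=5)
    print(
        f"{beta_learn:10.0f} {m:4d} {stats['retrieval_probability']:13.2f}"
        f" {stats['mean_length_fraction']:17.2f}"
    )
print(
    "\nRetrieval becomes reliable once the noise present during learning"
    "\nexceeds the noise present during retrieval (here beta_retr = 10);"
    "\nthe price is the smaller number of storable associations m."
)
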