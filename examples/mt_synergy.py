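"""Multi-task synergy: does a correlated neighbour task help a sparse target?

Runs the packaged synergy experiment twice — once with strongly correlated
series effects across targets (rho = 0.9) and once with uncorrelated ones
(rho = 0) — and reports per-trial test MAE of a single-target DNN trained on
the sparse target's ~20 training labels alone versus a multi-target DNN that
also sees five densely-labelled targets through the masked loss.
"""

from potbench.benchmark import mt_synergy_experiment

for rho in (0.9, 0.0):
    result = mt_synergy_experiment(seed=1, rho=rho)
    print(f"rho = {rho}: sparse target has {result.n_sparse_labels} labels")
    for i, (st, mt) in enumerate(zip(result.st_mae, result.mt_mae)):
        print(f"  trial {i}: ST-DNN MAE {st:.3f}  MT-DNN MAE {mt:.3f}")
    print(
        f"  MT wins {result.wins}/3 trials, "
        f"mean MAE advantage {result.mean_advantage:+.3f} pKi\n"
    )

print(
    "With correlated tasks the jointly trained network transfers series-level\n"
    "information to the sparse target and should win most trials; without\n"
    "correlation the advantage should shrink below the 0.1 pKi relevance\n"
    "threshold (a residual benefit can remain because substituent effects are\n"
    "shared across targets in the generative model)."
)
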