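"""Exact enumeration oracle vs the Monte Carlo engine (toy discrete mode).

In toy mode CD4 and viral load are binary states, so the counterfactual risk
under any strategy can be computed exactly by dynamic programming over the
state distribution.  This script compares that exact risk with the Monte
Carlo g-formula engine run from the same true coefficients — the core
correctness check of the simulator.
"""

import numpy as np

import artswitch as a
from artswitch.synth import exact_risk, toy_baseline_frame, true_model_set

params = a.GeneratorParams(n=100, K_max=5, seed=1).with_toy_defaults()
models = true_model_set(params)
pool = toy_baseline_frame(params, 20000, np.random.default_rng(99))
config = a.SimConfig(n_mc=20000, horizon_K=5, seed=4, toy_mode=True)

print(f"{'strategy':20s}  {'exact':>8s}  {'monte carlo':>11s}")
for strategy in a.default_strategies():
    exact = exact_risk(params, strategy, 5).risk_at(5)
    mc = a.simulate(models, pool, strategy, config,
                    rng=np.random.default_rng(7)).risk_5yr
    print(f"{strategy.name:20s}  {100 * exact:7.2f}%  {100 * mc:10.2f}%")
# agreement within Monte Carlo error (~0.4 percentage points at n_mc=20,000)
# validates the simulator's within-interval update order and strategy logic
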