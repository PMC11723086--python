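"""Hybrid adaptive DE vs classic DE/rand/1/bin on the 2-D Rastrigin function.

The hybrid variant adapts F and CR from the convergence indicator and the
population diversity, and switches mutation strategies across run stages
(rand/1 -> current-to-best/1 -> best/1 & best/2).
"""

import numpy as np

from kernelid import HDEConfig, optimize


def rastrigin(x):
    return float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))


hde_best, de_best = [], []
for seed in range(15):
    common = dict(bounds=((-5.12, 5.12),) * 2, population_size=20, generations=50, seed=seed)
    hde_best.append(optimize(rastrigin, HDEConfig(**common)).fun)
    de_best.append(
        optimize(
            rastrigin,
            HDEConfig(adaptation="fixed", strategy_schedule=((0.0, "rand1"),), **common),
        ).fun
    )

print(f"mean best fitness over 15 seeds (global optimum is 0):")
print(f"  adaptive (HDE): {np.mean(hde_best):.2e}")
print(f"  classic DE    : {np.mean(de_best):.2e}")
print("\nThe adaptive controls keep step sizes heterogeneous, avoiding the")
print("premature convergence that occasionally traps the fixed-parameter run.")
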