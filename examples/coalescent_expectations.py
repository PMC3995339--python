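"""Check coalescent simulations against closed-form expectations.

For a contemporaneous sample of n=15 from a panmictic population of constant
size N=1000 (pairwise coalescence rate 1/(2N) per generation), theory gives
E[TMRCA] = 4N(1 - 1/n) and E[total tree length] = 4N * sum_{k<n} 1/k.
"""

import numpy as np

from genomesim import Demography, SampleConfig, simulate_genealogy, tmrca, total_branch_length

N, n, reps = 1000.0, 15, 5000
rng = np.random.default_rng(1)
dem = Demography.constant(N)
sample = SampleConfig.contemporaneous(n)

tm, tl = [], []
for _ in range(reps):
    g = simulate_genealogy(sample, dem, rng=rng)
    tm.append(tmrca(g))
    tl.append(total_branch_length(g))

print(f"mean TMRCA        {np.mean(tm):8.1f}  (theory {4 * N * (1 - 1 / n):8.1f}) generations")
print(f"mean tree length  {np.mean(tl):8.1f}  (theory {4 * N * sum(1 / k for k in range(1, n)):8.1f}) generations")
print("The simulated means should sit within Monte-Carlo error of theory.")
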