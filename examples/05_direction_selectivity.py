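"""Direction-selectivity index and its permutation test.

Simulates moving-bar responses at 8 directions for tuned and untuned
cells, computes the SVD-based vector-sum direction-selectivity index and
a trial-label shuffle p-value for each, and checks the false-positive
rate on the untuned subpopulation.
"""

import numpy as np

import hybridsi as hs

strengths = np.r_[np.zeros(30), np.full(10, 0.8)]  # 30 untuned, 10 tuned
cells = hs.simulate_direction_trials(len(strengths), strengths, n_trials=5,
                                     noise_sd=0.15, seed=0)

results = [hs.ds_test(c, n_perm=500, seed=i) for i, c in enumerate(cells)]
dsi = np.array([r.ds_index for r in results])
pval = np.array([r.p_value for r in results])

print(f"untuned cells: median DSI {np.median(dsi[:30]):.3f}, "
      f"flagged at p<0.05: {(pval[:30] < 0.05).sum()}/30")
print(f"tuned cells:   median DSI {np.median(dsi[30:]):.3f}, "
      f"flagged at p<0.05: {(pval[30:] < 0.05).sum()}/10")
# DSI is the normalized vector sum of the tuning curve (1 = all response
# in one direction, 0 = symmetric).  Under the shuffle null ~5% of
# untuned cells are flagged; strongly tuned cells are detected reliably.

r = results[-1]
print("example tuned cell tuning curve:",
      np.round(r.directional_component, 2))
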