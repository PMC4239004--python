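"""Train a funnel-sculpted pair potential and check it recovers the funnel.

Plants a linear energy-distance funnel (targets d = phi . theta* for a
known coefficient table theta*) on three synthetic ensembles, trains the
1680-parameter spline potential by solving the regularized QP, and reports
the per-protein Pearson correlation between trained energy gaps and the
planted targets — near 1.0 means the sculpting recovered the funnel.
"""

import numpy as np

from funnelpot import SynthConfig, fit_potential, gen_planted_funnel, pearson
from funnelpot.training import featurize

cfg = SynthConfig(n_res=30, n_decoys=40, noise_grid=[4.0, 6.0], seed=2)
ensembles, targets = gen_planted_funnel(cfg, n_ensembles=3)

result = fit_potential(ensembles, targets=targets, beta=1e-8, c_bound=1.0)
print(f"solver: {result.solver_status}, objective {result.objective:.3g}")
print(f"proportionality constants c_i: {np.round(result.c, 3)}")

x = result.params.flat
for i, (e, t) in enumerate(zip(ensembles, targets)):
    Phi, _ = featurize(e, d_measure=None)
    corr = pearson(Phi @ x, t)
    print(f"protein {i}: corr(trained energy gap, planted distance) "
          f"= {corr:.4f}")
print("\nEach correlation ~1.0: the QP reproduced the planted funnel up to "
      "the per-protein scale c_i >= 1.")
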