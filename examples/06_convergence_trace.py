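"""Watch the alternating solver converge on one binary problem.

Each local domain is relaxed by closed-form block updates until the relative
objective change drops below 1e-4; the recorded trace is non-increasing by
construction, and convergence typically takes only a handful of iterations.
"""

import numpy as np

from ldg import (
    LDGHyperparams,
    SyntheticConfig,
    fit_binary,
    generate_multisubject_dataset,
)

X, y, _ = generate_multisubject_dataset(SyntheticConfig(seed=0))
model = fit_binary(X, np.where(y == 0, 1.0, -1.0), LDGHyperparams())

iters = model.per_domain_iterations
print(f"local domains: {len(model.local_domains)}")
print(f"inner iterations per domain: median {np.median(iters):.0f}, "
      f"max {iters.max()}, total {model.iterations}")
first = model.objective_trace[0]
print("objective trace of the first domain:",
      np.array2string(first, precision=3))
drops = [float(tr[0] - tr[-1]) for tr in model.objective_trace]
print(f"objective decreased in every domain block "
      f"(largest single-block drop {max(drops):.2f})")
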