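"""Estimate cell-type fractions of bulk samples from a reference matrix.

Builds a five-cell-type reference, mixes it into bulk profiles with known
weights plus measurement noise, and recovers the weights by constrained
least squares (nonnegative, summing to one).
"""

import numpy as np
import pandas as pd

import epitoc as e

rng = np.random.default_rng(1)
probes = pd.Index([f"cg{i:04d}" for i in range(300)], name="probe_id")
ref = e.CellTypeReference(
    pd.DataFrame(rng.uniform(0, 1, (300, 5)), index=probes,
                 columns=["Bcell", "Tcell", "Mono", "NK", "Gran"])
)

w_true = rng.dirichlet(np.ones(5), size=4)          # four bulk samples
bulk = np.clip(ref.values.to_numpy() @ w_true.T + rng.normal(0, 0.02, (300, 4)), 0, 1)
beta = e.BetaMatrix(pd.DataFrame(bulk, index=probes,
                                 columns=[f"s{i}" for i in range(4)]))

fractions = e.estimate_cell_fractions(beta, ref)
for s in beta.sample_ids:
    est = fractions.weights.loc[s].to_numpy()
    true = w_true[list(beta.sample_ids).index(s)]
    print(f"{s}: est={np.round(est, 3)}  true={np.round(true, 3)}  "
          f"rms-resid={fractions.fit_residual.loc[s]:.4f}")
# each row is a point on the probability simplex; the residual measures how
# well the reference profiles explain the bulk sample.
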