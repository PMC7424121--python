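"""Independent numerical oracles used by the inference tests.

These deliberately avoid the code paths they check: the marginal likelihood
is computed by Gauss-Hermite quadrature over a single grouping factor's
intercepts, not by the Laplace approximation under test.
"""

import numpy as np
from scipy import special

from morphcp.inference import ModelSpec, _aggregate_choices, _build_design


def quadrature_loglik(trials, beta, sigma_participant, spec: ModelSpec, n_nodes=101):
    """Exact marginal binomial log-likelihood with a participant intercept
    integrated out per participant by Gauss-Hermite quadrature."""
    agg = _aggregate_choices(trials)
    design = _build_design(agg, spec, weights=agg["n"].to_numpy(float))
    eta0 = design.X @ np.asarray(beta)
    k = agg["k"].to_numpy(float)
    n = agg["n"].to_numpy(float)
    const = float(
        np.sum(special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1))
    )
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
    total = const
    for pid in agg["participant_id"].unique():
        idx = np.flatnonzero((agg["participant_id"] == pid).to_numpy())
        vals = []
        for t, w in zip(nodes, wts):
            eta = eta0[idx] + np.sqrt(2.0) * sigma_participant * t
            ll = float(np.sum(k[idx] * eta - n[idx] * np.logaddexp(0.0, eta)))
            vals.append(np.log(w) + ll)
        total += float(special.logsumexp(vals)) - 0.5 * np.log(np.pi)
    return total
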