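"""Parameter transforms between the unconstrained (sampling) scale and the
bounded (model) scale.

All bounded parameters live in (0, hi) and are mapped through the standard
normal CDF: theta = hi * Phi(z).  This is the same transform used by the
hierarchical sampler and by the synthetic-cohort generator, so group-level
Normal(mean, sd) draws on the unconstrained scale induce the individual
parameter distributions the fitter assumes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

# Upper bound of each parameter's (0, hi) support.
PARAM_UPPER = {
    "tau": 20.0,
    "w_ns": 10.0,
    "w_s": 10.0,
    "kappa": 1.0,
    "alpha": 1.0,
    "alpha_al": 1.0,
    "alpha_mis": 1.0,
    "alpha_al_ac": 1.0,
    "alpha_al_re": 1.0,
    "alpha_mis_ac": 1.0,
    "alpha_mis_re": 1.0,
}


def to_constrained(z, name: str):
    """Map unconstrained value(s) ``z`` to the bounded scale of parameter ``name``."""
    return PARAM_UPPER[name] * ndtr(np.asarray(z, dtype=float))


def to_unconstrained(theta, name: str):
    """Inverse of :func:`to_constrained`."""
    hi = PARAM_UPPER[name]
    theta = np.asarray(theta, dtype=float)
    if np.any((theta <= 0) | (theta >= hi)):
        raise ValueError(f"{name} must lie strictly inside (0, {hi})")
    return ndtri(theta / hi)
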