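"""Independent oracles for the Markov engine.

The microsimulation draws individual state paths from the same per-cycle
transition matrices and estimates occupancy by Monte Carlo; it shares no
code with the cohort-propagation path it checks.
"""

from __future__ import annotations

import numpy as np


def microsimulate(
    T: np.ndarray, start_state: int, n_sim: int, seed: int = 0
) -> np.ndarray:
    """Empirical occupancy from individual path simulation.

    ``T`` has shape (C, S, S); returns occupancy of shape (C+1, S) as
    fractions of the simulated population.
    """
    C, S, _ = T.shape
    rng = np.random.default_rng(seed)
    state = np.full(n_sim, start_state, dtype=np.int64)
    occ = np.zeros((C + 1, S))
    occ[0, start_state] = 1.0
    for c in range(C):
        cum = np.cumsum(T[c], axis=1)
        u = rng.random(n_sim)
        new = np.empty_like(state)
        for s in np.unique(state):
            mask = state == s
            new[mask] = np.searchsorted(cum[s], u[mask], side="right")
        state = np.minimum(new, S - 1)
        occ[c + 1] = np.bincount(state, minlength=S) / n_sim
    return occ
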