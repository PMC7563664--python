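"""Independent brute-force oracles used by the tests.

The grid oracle maximizes the transmission log-likelihood over the full
3-D product grid (alpha x pi_E x pi_R, step 0.001).  Because the
likelihood separates by sire variety,

    lnL(alpha, pi_E, pi_R) = g_E(alpha, pi_E) + g_R(alpha, pi_R),

the maximum over the product grid equals
max_alpha [max_piE g_E + max_piR g_R]; this is evaluated exactly (same
maximizer and value as scanning all ~1e9 grid points) but in ~2e6 cells.
It shares no code with the fitted gradient ascent.
"""

from __future__ import annotations

import numpy as np

ALPHA_BOUND = 0.495


def grid_loglik_max(n: np.ndarray, step: float = 0.001) -> float:
    """Max log-likelihood over the (alpha, pi_E, pi_R) grid at ``step``."""
    n = np.asarray(n)
    alphas = np.arange(-ALPHA_BOUND, ALPHA_BOUND + step / 2, step)
    pis = np.arange(0.0, 1.0 + step / 2, step)

    total = np.zeros_like(alphas)
    any_active = False
    for s in range(2):
        ns = n[:, :, s]
        if ns.sum() == 0:
            continue
        any_active = True
        # g_s(alpha, pi) on the grid: accumulate n * ln p cell by cell
        g = np.zeros((alphas.size, pis.size))
        pm_by_d = {2: np.full_like(alphas, 1.0), 1: 0.5 + alphas, 0: np.zeros_like(alphas)}
        with np.errstate(divide="ignore", invalid="ignore"):
            for d in range(3):
                pm = pm_by_d[d][:, None]
                qm = 1.0 - pm
                probs = [qm * (1.0 - pis)[None, :],
                         pm * (1.0 - pis)[None, :] + qm * pis[None, :],
                         pm * pis[None, :]]
                for o in range(3):
                    c = ns[d, o]
                    if c:
                        g += c * np.log(probs[o])
        total += np.nanmax(np.where(np.isfinite(g), g, -np.inf), axis=1)
    if not any_active:
        return 0.0
    return float(total.max())


def random_counts(rng: np.random.Generator, max_total: int = 60) -> np.ndarray:
    """Random compatible TransmissionCounts array with >=1 het-dam family."""
    n = np.zeros((3, 3, 2), dtype=np.int64)
    cells = [(d, o, s) for d in range(3) for o in range(3) for s in range(2)
             if not ((d == 2 and o == 0) or (d == 0 and o == 2))]
    total = int(rng.integers(5, max_total + 1))
    for _ in range(total):
        d, o, s = cells[rng.integers(len(cells))]
        n[d, o, s] += 1
    if n[1].sum() == 0:  # force at least one informative family
        n[1, 1, 0] += 1
    return n
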