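"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they check: naive
Lance-Williams Ward agglomeration, brute-force Mann-Whitney pair counting,
hand Holm step-down, direct chi-square summation, and rank-then-Pearson
Spearman.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dietnet import default_simulation_config, simulate_cohort
from dietnet.ffq_ingest import FOOD_GROUPS


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def small_cohort():
    """A reduced four-stratum cohort for fast end-to-end tests."""
    from dietnet.synthetic_cohort import SimulationConfig, StratumSpec

    cfg = default_simulation_config(seed=11)
    strata = tuple(
        StratumSpec(
            name=s.name,
            n={"underweight": 40, "eutrophy": 120, "overweight": 45, "obesity": 35}[s.name],
            target_spearman=s.target_spearman,
            marginal_log_median=s.marginal_log_median,
            marginal_log_sd=s.marginal_log_sd,
        )
        for s in cfg.strata
    )
    small = SimulationConfig(
        strata=strata, demographic_probs=cfg.demographic_probs, seed=11
    )
    return simulate_cohort(small)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort (1496 participants)."""
    return simulate_cohort(default_simulation_config(seed=3))


# ----------------------------------------------------------------- oracles
def naive_ward_heights(X: np.ndarray) -> np.ndarray:
    """O(n^3) Ward agglomeration via the Lance-Williams recurrence.

    Operates on squared Euclidean distances and reports sqrt heights
    (Ward.D2), merging the globally closest active pair at each step.
    """
    n = X.shape[0]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2).astype(float)
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    heights = []
    D = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = d2[i, j]
    next_id = n
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                key = (min(i, j), max(i, j))
                if best is None or D[key] < best[0]:
                    best = (D[key], key)
        dmin, (i, j) = best
        heights.append(np.sqrt(dmin))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = D[(min(i, k), max(i, k))]
            djk = D[(min(j, k), max(j, k))]
            dij = dmin
            D[(min(new, k), max(new, k))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        active = [a for a in active if a not in (i, j)] + [new]
        sizes[new] = ni + nj
    return np.array(heights)


def brute_force_mannwhitney_u(x, y) -> float:
    """U of x by exhaustive pair counting (ties count half)."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def hand_holm(p: list[float]) -> list[float]:
    """Step-down Holm by direct construction."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        val = min((m - rank) * p[i], 1.0)
        running = max(running, val)
        adj[i] = running
    return adj


def chi_square_oracle(obs: np.ndarray) -> tuple[float, int]:
    """Sum of (O-E)^2/E with expected counts from the margins."""
    obs = np.asarray(obs, dtype=float)
    E = obs.sum(1, keepdims=True) @ obs.sum(0, keepdims=True) / obs.sum()
    return float(((obs - E) ** 2 / E).sum()), (obs.shape[0] - 1) * (obs.shape[1] - 1)


def spearman_oracle(x, y) -> float:
    """Average-rank both vectors, then plain Pearson."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def make_block(rng: np.random.Generator, n: int, target: np.ndarray) -> pd.DataFrame:
    """Gaussian-copula block with given Spearman target on the 14 groups.

    Non-PSD targets are repaired the same way the generator repairs them.
    """
    import warnings

    from dietnet.synthetic_cohort import spearman_to_pearson

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, _ = spearman_to_pearson(np.asarray(target, dtype=float))
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(len(r)))
    z = rng.standard_normal((n, len(r))) @ chol.T
    return pd.DataFrame(np.exp(4.0 + 0.8 * z), columns=list(FOOD_GROUPS))
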