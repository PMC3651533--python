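"""Shared fixtures and independent oracles.

The oracles here deliberately use the slow, definition-level route
(triple loops, pair counting, direct quadrature) so they stay
independent of the vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate, stats

import triroc as tr


# ---------------------------------------------------------------------------
# oracles


def brute_force_vus(x, y, z, tie_rule="partial") -> float:
    """O(n1*n2*n3) triple loop over the ordering kernel.

    Accumulates integer weights (6/3/1 for strict, single-tie, triple
    tie) so the result is bit-exact against any summation order.
    """
    total = 0
    for xi in x:
        for yj in y:
            for zk in z:
                if xi < yj < zk:
                    total += 6
                elif tie_rule == "partial":
                    if xi == yj < zk or xi < yj == zk:
                        total += 3
                    elif xi == yj == zk:
                        total += 1
    return total / (6.0 * len(x) * len(y) * len(z))


def true_vus_normal(m1, m2, m3, s1=1.0, s2=1.0, s3=1.0) -> float:
    """P(X < Y < Z) for independent normals, by direct quadrature."""
    val, _ = integrate.quad(
        lambda y: (
            stats.norm.pdf(y, m2, s2)
            * stats.norm.cdf((y - m1) / s1)
            * stats.norm.sf((y - m3) / s3)
        ),
        -30,
        30,
        limit=200,
    )
    return val


def brute_force_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Adjusted P by the step-up definition: the smallest alpha at
    which each hypothesis is rejected, i.e. min over k at or above the
    hypothesis' rank of (m - k + 1) * p_(k)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            (m - k) * sorted_p[k] for k in range(i, m)
        )
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def brute_force_kendall_tau(x, y) -> float:
    """Tau-b by explicit concordant/discordant pair counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def default_cohort() -> tr.CohortTable:
    """One default synthetic cohort (40/23/40, complete marker)."""
    return tr.generate_cohort(tr.CohortConfig(seed=11, missing_rate=0.0))


@pytest.fixture(scope="session")
def small_triple() -> tr.OrderedMarkerTriple:
    rng = np.random.default_rng(5)
    return tr.OrderedMarkerTriple(
        rng.normal(0.0, 1.0, 12),
        rng.normal(0.8, 1.0, 9),
        rng.normal(1.6, 1.0, 11),
    )
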