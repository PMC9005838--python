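"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately use brute force (pairwise loops,
dense Riemann grids, exact enumeration) so they share no code path with the
package implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mroc import PredictionSample


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_sample(rng: np.random.Generator, n: int | None = None, ties: bool = False) -> PredictionSample:
    """A random prediction sample with both outcome classes present."""
    if n is None:
        n = int(rng.integers(2, 51))
    while True:
        risks = rng.random(n)
        if ties:
            risks = np.round(risks, int(rng.integers(1, 3)))
        outcomes = (rng.random(n) < 0.5).astype(float)
        if 0 < outcomes.sum() < n:
            return PredictionSample(risks, outcomes)


def pair_count_auc(risks: np.ndarray, outcomes: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC by brute-force pair counting."""
    cases = risks[outcomes == 1]
    controls = risks[outcomes == 0]
    diff = cases[:, None] - controls[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def pairwise_cstat(risks: np.ndarray) -> float:
    """Model-based concordance by brute force over all ordered pairs.

    Pair (i, j) carries case-control weight pi_i (1 - pi_j); concordant
    pairs count fully and risk-tied pairs (including i = j) count half.
    """
    r = np.asarray(risks, dtype=float)
    w = r[:, None] * (1.0 - r[None, :])
    gt = r[:, None] > r[None, :]
    eq = r[:, None] == r[None, :]
    num = float(np.sum(w * gt) + 0.5 * np.sum(w * eq))
    den = float(r.sum() * (1.0 - r).sum())
    return num / den


def grid_abs_diff(c1, c2, points: int = 1_000_000) -> float:
    """Riemann-midpoint estimate of the integrated absolute curve difference."""
    t = (np.arange(points) + 0.5) / points
    return float(np.abs(c1(t) - c2(t)).mean())


def enumerated_mean_abs_binom_dev(n: int, p: float = 0.5, conditional: bool = True) -> float:
    """Exact E|Binomial(n, p)/n - p| by enumeration over all outcomes.

    With ``conditional=True`` the expectation conditions on 0 < k < n,
    matching a null simulation that redraws single-class outcome vectors.
    """
    from math import comb

    ks = range(1, n) if conditional else range(n + 1)
    mass = sum(comb(n, k) * p**k * (1 - p) ** (n - k) for k in ks)
    total = sum(
        comb(n, k) * p**k * (1 - p) ** (n - k) * abs(k / n - p) for k in ks
    )
    return total / mass
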