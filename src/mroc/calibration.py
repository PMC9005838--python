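"""Monte-Carlo unified test of moderate calibration.

A risk model is *moderately calibrated* in a population when, among subjects
with predicted risk p, the event fraction is p.  Moderate calibration is
equivalent to the conjunction of two testable conditions:

* **mean calibration** — the average predicted risk equals the event rate
  (statistic ``An = |mean(Y) - mean(pi)|``), and
* **ROC/mROC equality** — the empirical ROC curve coincides with the
  model-based ROC curve (statistic ``Bn``, the integrated absolute
  difference between the two curves).

Null distributions of both statistics are simulated by redrawing outcomes
``Y* ~ Bernoulli(pi_i)`` from the predicted risks, which is exactly the
data-generating law under the null.  Each component p-value is a one-tailed
Monte-Carlo p-value; the two are combined with Fisher's statistic
``Un = -2(log pA + log pB)``, whose null law is *not* chi-square(4) because
``An`` and ``Bn`` share the data.  The paired null replicates provide the
dependence structure: each replicate is scored against the null sample to
give null (pA*, pB*) pairs, and the first two moments of
``U* = -2(log pA* + log pB*)`` are matched to a scaled chi-square
(Brown-style moment matching) to produce the unified p-value.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import chi2

from ._version import __version__
from .curves import empirical_roc, integrated_abs_diff, mroc
from .sample import PredictionSample

__all__ = [
    "NullDistribution",
    "CalibrationTestResult",
    "UnifiedPValue",
    "mean_calibration_stat",
    "roc_equality_stat",
    "simulate_null_distribution",
    "component_pvalues",
    "unified_pvalue",
    "run_calibration_test",
]

logger = logging.getLogger(__name__)

# rows of simulated outcomes processed per block; fixed so that the random
# stream layout (and hence every result) depends only on (risks, M, seed)
_BLOCK_ROWS = 512

DEFAULT_M = 100_000


def mean_calibration_stat(sample: PredictionSample) -> float:
    """``An = |sum(Y_i - pi_i)| / n``, the mean-calibration statistic."""
    return float(abs(np.sum(sample.outcomes - sample.risks)) / sample.n)


def roc_equality_stat(sample: PredictionSample) -> float:
    """``Bn``: integrated absolute difference between empirical ROC and mROC."""
    return integrated_abs_diff(empirical_roc(sample), mroc(sample.risks))


@dataclass(frozen=True)
class NullDistribution:
    """Paired Monte-Carlo null samples of (An*, Bn*) for fixed risks.

    ``a_samples[k]`` and ``b_samples[k]`` come from the same simulated
    outcome vector, which is what lets the unified test estimate the
    dependence between the two statistics.
    """

    a_samples: np.ndarray
    b_samples: np.ndarray
    m: int
    seed: int
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.a_samples, dtype=float)
        b = np.asarray(self.b_samples, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("a_samples and b_samples must be paired 1-d vectors")
        if a.shape[0] != self.m or self.m < 100:
            raise ValueError("need at least M = 100 paired null replicates")
        if a.min() < 0 or b.min() < 0 or a.max() > 1 or b.max() > 1:
            raise ValueError("null statistics must lie in [0, 1]")
        a.setflags(write=False)
        b.setflags(write=False)
        object.__setattr__(self, "a_samples", a)
        object.__setattr__(self, "b_samples", b)

    def to_tsv(self, path) -> None:
        """Audit export: one (An*, Bn*) pair per line."""
        with open(path, "w") as fh:
            fh.write("a_null\tb_null\n")
            for a, b in zip(self.a_samples, self.b_samples):
                fh.write(f"{float(a)!r}\t{float(b)!r}\n")


class _NullEngine:
    """Vectorised computation of (An*, Bn*) for blocks of simulated outcomes.

    The mROC curve and the tie-group layout of the risks are fixed per test,
    so they are precomputed once; each block of Bernoulli outcome draws then
    reduces to cumulative sums over tie groups and an exact piecewise-linear
    integration against the fixed mROC, all in array operations.
    """

    def __init__(self, risks: np.ndarray):
        risks = np.asarray(risks, dtype=float)
        m_curve = mroc(risks)  # validates risks
        order = np.argsort(-risks, kind="stable")
        self.r_desc = risks[order]
        first = np.empty(self.r_desc.shape[0], dtype=bool)
        first[0] = True
        np.not_equal(self.r_desc[1:], self.r_desc[:-1], out=first[1:])
        self.starts = np.flatnonzero(first)
        sizes = np.diff(np.append(self.starts, self.r_desc.shape[0]))
        self.cum_sizes = np.cumsum(sizes)
        self.n = int(self.r_desc.shape[0])
        self.mean_risk = float(risks.mean())
        self.mroc_curve = m_curve
        self.mx = m_curve.fpr
        self.my = m_curve.tpr

    def draw_outcomes(self, rng: np.random.Generator, rows: int) -> np.ndarray:
        """Bernoulli outcome draws aligned with the descending-sorted risks."""
        return rng.random((rows, self.n)) < self.r_desc

    def degenerate(self, y: np.ndarray) -> np.ndarray:
        n1 = y.sum(axis=1)
        return (n1 == 0) | (n1 == self.n)

    def stats(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(An*, Bn*) for each row of outcomes; no row may be degenerate.

        The union of the two curves' fpr breakpoints comes from one stable
        argsort of the concatenated vertex lists; the running count of
        ROC-origin entries then gives, for every union segment, the index
        of the ROC (and mROC) linear piece covering it, so both curves are
        evaluated exactly at the segment endpoints without searching.
        """
        a = np.abs(y.mean(axis=1) - self.mean_risk)

        pos = np.add.reduceat(y, self.starts, axis=1).cumsum(axis=1, dtype=float)
        n1 = pos[:, -1]
        neg = self.cum_sizes[None, :] - pos
        n0 = float(self.n) - n1
        tp = pos / n1[:, None]
        fp = neg / n0[:, None]
        rows = y.shape[0]
        zeros = np.zeros((rows, 1))
        rx = np.concatenate([zeros, fp], axis=1)
        ry = np.concatenate([zeros, tp], axis=1)
        rx[:, -1] = 1.0
        ry[:, -1] = 1.0

        p = rx.shape[1]  # vertices per curve (ROC and mROC alike)
        xs = np.concatenate([rx, np.broadcast_to(self.mx, (rows, p))], axis=1)
        order = xs.argsort(axis=1, kind="stable")
        xs = np.take_along_axis(xs, order, axis=1)
        h = np.diff(xs, axis=1)
        xl = xs[:, :-1]
        xr = xs[:, 1:]
        # running count of ROC-origin breakpoints up to each sorted position
        cum = np.cumsum(order < p, axis=1)[:, :-1]
        jr = np.clip(cum - 1, 0, p - 2)
        jm = np.clip(np.arange(1, 2 * p)[None, :] - cum - 1, 0, p - 2)

        flat = jr + (np.arange(rows) * p)[:, None]
        x0 = rx.ravel().take(flat)
        y0 = ry.ravel().take(flat)
        dx = rx.ravel().take(flat + 1) - x0
        sl = (ry.ravel().take(flat + 1) - y0) / np.where(dx > 0.0, dx, 1.0)
        mx0 = self.mx[jm]
        my0 = self.my[jm]
        mdx = self.mx[jm + 1] - mx0
        msl = (self.my[jm + 1] - my0) / np.where(mdx > 0.0, mdx, 1.0)

        dl = (y0 + (xl - x0) * sl) - (my0 + (xl - mx0) * msl)
        dr = (y0 + (xr - x0) * sl) - (my0 + (xr - mx0) * msl)
        adl = np.abs(dl)
        adr = np.abs(dr)
        tot = adl + adr
        crossed = np.where(tot > 0.0, (dl * dl + dr * dr) / np.where(tot > 0.0, tot, 1.0), 0.0)
        per = np.where(dl * dr >= 0.0, tot, crossed)
        b = 0.5 * np.sum(h * per, axis=1)
        return a, b


def simulate_null_distribution(risks: np.ndarray, M: int = DEFAULT_M, seed: int = 0) -> NullDistribution:
    """Simulate M paired (An*, Bn*) draws under the calibration null.

    Outcomes are redrawn as independent Bernoulli(pi_i) against the *fixed*
    risks; the mROC curve is precomputed once since it depends only on the
    risks.  Draws in which all simulated outcomes coincide (empirical ROC
    undefined) are redrawn from the same stream and counted in
    ``n_degenerate``; a warning is raised if they exceed 0.1% of M.
    Bit-identical output for identical ``(risks, M, seed)``.
    """
    if M < 100:
        raise ValueError(f"need M >= 100 null replicates, got {M}")
    engine = _NullEngine(risks)
    n_blocks = -(-M // _BLOCK_ROWS)
    streams = np.random.SeedSequence(seed).spawn(n_blocks)
    a_out = np.empty(M)
    b_out = np.empty(M)
    n_degenerate = 0
    done = 0
    next_report = M // 10 if M >= 10 else M
    for blk, stream in enumerate(streams):
        rows = min(_BLOCK_ROWS, M - blk * _BLOCK_ROWS)
        rng = np.random.default_rng(stream)
        y = engine.draw_outcomes(rng, rows)
        bad = engine.degenerate(y)
        while bad.any():
            n_degenerate += int(bad.sum())
            y[bad] = engine.draw_outcomes(rng, int(bad.sum()))
            bad = engine.degenerate(y)
        a, b = engine.stats(y)
        a_out[done : done + rows] = a
        b_out[done : done + rows] = b
        done += rows
        if done >= next_report:
            logger.debug("null simulation: %d / %d replicates", done, M)
            next_report += max(M // 10, 1)
    if n_degenerate > 0.001 * M:
        warnings.warn(
            f"{n_degenerate} degenerate null draws (> 0.1% of M={M}) were "
            "redrawn; the predicted risks are extreme enough that the "
            "conditional null may be distorted",
            RuntimeWarning,
        )
    return NullDistribution(a_out, b_out, m=M, seed=seed, n_degenerate=n_degenerate)


def component_pvalues(nd: NullDistribution, a_stat: float, b_stat: float) -> tuple[float, float]:
    """One-tailed Monte-Carlo p-values for the observed An and Bn.

    ``p = (1 + #{null >= observed}) / (M + 1)``: the add-one smoothing keeps
    p strictly positive and exactly uniform on the 1/(M+1) grid under the
    null; ties between the observed statistic and null draws count against
    the observation (conservative).
    """
    p_a = (1.0 + np.count_nonzero(nd.a_samples >= a_stat)) / (nd.m + 1.0)
    p_b = (1.0 + np.count_nonzero(nd.b_samples >= b_stat)) / (nd.m + 1.0)
    return float(p_a), float(p_b)


class UnifiedPValue(NamedTuple):
    u_stat: float
    df_matched: float
    scale_matched: float
    p_unified: float


def unified_pvalue(nd: NullDistribution, p_a: float, p_b: float) -> UnifiedPValue:
    """Dependence-adjusted Fisher combination of the two component p-values.

    Each null replicate is scored against the whole null sample
    (self-inclusive empirical CDF, so null p-values live on the 1/M grid and
    never vanish), giving paired null (pA*, pB*) and hence null draws of
    ``U* = -2(log pA* + log pB*)``.  The null law of ``Un`` is approximated
    by ``c * chi2(f)`` with the scale and degrees of freedom matched to the
    mean and variance of ``U*``; with independent components this recovers
    Fisher's chi-square with 4 df (c -> 1, f -> 4).
    """
    if not (0.0 < p_a <= 1.0 and 0.0 < p_b <= 1.0):
        raise ValueError("component p-values must lie in (0, 1]")
    u_stat = -2.0 * (np.log(p_a) + np.log(p_b))
    m = nd.m
    sa = np.sort(nd.a_samples)
    sb = np.sort(nd.b_samples)
    pa_star = (m - np.searchsorted(sa, nd.a_samples, side="left")) / m
    pb_star = (m - np.searchsorted(sb, nd.b_samples, side="left")) / m
    u_star = -2.0 * (np.log(pa_star) + np.log(pb_star))
    e_bar = float(u_star.mean())
    v_bar = float(u_star.var(ddof=1))
    if e_bar <= 0.0 or v_bar <= 0.0:
        raise ValueError(
            f"pathological null U* sample (mean={e_bar:.3g}, var={v_bar:.3g}); "
            "cannot moment-match a chi-square"
        )
    scale = v_bar / (2.0 * e_bar)
    df = 2.0 * e_bar * e_bar / v_bar
    p_unified = float(chi2.sf(u_stat / scale, df))
    # Un = 0 only when both component p-values are 1; sf(0) = 1 regardless
    return UnifiedPValue(float(u_stat), df, scale, p_unified)


@dataclass(frozen=True)
class CalibrationTestResult:
    """Complete output of the unified moderate-calibration test."""

    a_stat: float
    b_stat: float
    p_a: float
    p_b: float
    u_stat: float
    df_matched: float
    scale_matched: float
    p_unified: float
    m: int
    seed: int
    n_degenerate: int = 0
    null_distribution: NullDistribution | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "a_stat": self.a_stat,
            "b_stat": self.b_stat,
            "p_a": self.p_a,
            "p_b": self.p_b,
            "u_stat": self.u_stat,
            "df_matched": self.df_matched,
            "scale_matched": self.scale_matched,
            "p_unified": self.p_unified,
            "m": self.m,
            "seed": self.seed,
            "n_degenerate": self.n_degenerate,
            "version": __version__,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def run_calibration_test(
    sample: PredictionSample,
    M: int = DEFAULT_M,
    seed: int = 0,
    keep_null: bool = False,
) -> CalibrationTestResult:
    """Run the full unified test of moderate calibration on one sample.

    Computes the observed ``An`` and ``Bn``, simulates the paired null with
    ``M`` replicates from ``seed``, and returns component and unified
    p-values.  Deterministic given ``(sample, M, seed)``.  Set ``keep_null``
    to retain the null samples for audit export.
    """
    sample.require_both_classes()
    a_stat = mean_calibration_stat(sample)
    b_stat = roc_equality_stat(sample)
    nd = simulate_null_distribution(sample.risks, M=M, seed=seed)
    p_a, p_b = component_pvalues(nd, a_stat, b_stat)
    unified = unified_pvalue(nd, p_a, p_b)
    return CalibrationTestResult(
        a_stat=a_stat,
        b_stat=b_stat,
        p_a=p_a,
        p_b=p_b,
        u_stat=unified.u_stat,
        df_matched=unified.df_matched,
        scale_matched=unified.scale_matched,
        p_unified=unified.p_unified,
        m=M,
        seed=seed,
        n_degenerate=nd.n_degenerate,
        null_distribution=nd if keep_null else None,
    )
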