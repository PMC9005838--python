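"""Classical calibration tests used as comparators.

Three established procedures against which the unified mROC test is
benchmarked:

* the Hosmer-Lemeshow chi-square test on risk-decile groups,
* the likelihood-ratio test of the logistic recalibration model
  ``logit P(Y=1) = alpha + beta * logit(pi)`` against the fixed
  ``(alpha, beta) = (0, 1)`` (weak calibration), and
* the one-sample two-tailed t-test of the differences ``Y - pi``
  (mean calibration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import logit
from scipy.stats import chi2

from .sample import PredictionSample

__all__ = [
    "GroupedCalibrationTable",
    "HosmerLemeshowResult",
    "LRRecalibrationResult",
    "hosmer_lemeshow_test",
    "lr_recalibration_test",
    "mean_calibration_ttest",
]

# clipping bound applied to risks before any logit; perturbs no statistic
# beyond ~1e-10 while keeping logs finite
_RISK_EPS = 1e-12


@dataclass(frozen=True)
class GroupedCalibrationTable:
    """Per-group observed/expected event counts for a grouped test.

    ``group_edges`` are the risk-quantile boundaries actually used (after
    any merging); ``n_merged`` counts groups that were folded into a
    neighbour because they carried no variance.
    """

    group_edges: np.ndarray
    counts: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    n_merged: int = 0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("lower\tupper\tcount\tobserved\texpected\n")
            for k in range(self.counts.shape[0]):
                fh.write(
                    f"{self.group_edges[k]!r}\t{self.group_edges[k + 1]!r}\t"
                    f"{int(self.counts[k])}\t{self.observed[k]!r}\t{self.expected[k]!r}\n"
                )


class HosmerLemeshowResult(NamedTuple):
    statistic: float
    df: int
    p_value: float
    table: GroupedCalibrationTable


class LRRecalibrationResult(NamedTuple):
    lr_statistic: float
    df: int
    p_value: float
    intercept_hat: float
    slope_hat: float


def hosmer_lemeshow_test(
    sample: PredictionSample, groups: int = 10, df_convention: str = "validation"
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow grouped chi-square test of calibration.

    Subjects are partitioned into ``groups`` bins by quantiles of predicted
    risk (linear-interpolation quantiles; a risk equal to a bin edge goes to
    the lower bin).  The statistic is ``sum (O - E)^2 / (E (1 - E/m))`` over
    bins with size m, observed events O and expected events E = sum(pi).
    Bins contributing no variance (all risks exactly 0 or 1) are merged with
    their neighbour; empty bins are dropped.

    ``df_convention="validation"`` (default) refers the statistic to
    chi-square with as many degrees of freedom as (post-merge) bins: in
    external validation no parameter was estimated from the sample, each
    bin contributes an approximately independent squared standardised
    binomial, and the classical G - 2 correction makes the test markedly
    anticonservative.  ``df_convention="development"`` applies the
    classical G - 2 of the original test for model-development data.
    """
    if groups < 2:
        raise ValueError("need at least 2 groups")
    if df_convention not in ("validation", "development"):
        raise ValueError("df_convention must be 'validation' or 'development'")
    risks = sample.risks
    y = sample.outcomes
    edges = np.quantile(risks, np.linspace(0.0, 1.0, groups + 1))
    # ties at an interior edge fall into the lower bin
    assign = np.searchsorted(edges[1:-1], risks, side="left")

    # bins as [count, observed, expected, lower, upper]; empty bins dropped
    bins: list[list[float]] = []
    for g in range(groups):
        mask = assign == g
        m = int(mask.sum())
        if m == 0:
            continue
        bins.append([m, float(y[mask].sum()), float(risks[mask].sum()),
                     float(edges[g]), float(edges[g + 1])])

    # merge zero-variance bins (E == 0 or E == m exactly) into a neighbour
    n_merged = 0
    while len(bins) > 1:
        idx = next((k for k, b in enumerate(bins) if b[2] <= 0.0 or b[2] >= b[0]), None)
        if idx is None:
            break
        j = idx + 1 if idx + 1 < len(bins) else idx - 1
        tgt = bins[j]
        src = bins.pop(idx)
        tgt[0] += src[0]
        tgt[1] += src[1]
        tgt[2] += src[2]
        tgt[3] = min(tgt[3], src[3])
        tgt[4] = max(tgt[4], src[4])
        n_merged += 1

    if len(bins) < 3:
        raise ValueError(
            f"only {len(bins)} usable risk groups after merging; the "
            "Hosmer-Lemeshow test needs at least 3"
        )
    counts_a = np.asarray([b[0] for b in bins], dtype=float)
    obs_a = np.asarray([b[1] for b in bins])
    exp_a = np.asarray([b[2] for b in bins])
    lowers = [b[3] for b in bins]
    uppers = [b[4] for b in bins]
    var = exp_a * (1.0 - exp_a / counts_a)
    statistic = float(np.sum((obs_a - exp_a) ** 2 / var))
    df = len(bins) - (0 if df_convention == "validation" else 2)
    p_value = float(chi2.sf(statistic, df))
    table = GroupedCalibrationTable(
        group_edges=np.asarray(lowers + [uppers[-1]]),
        counts=counts_a.astype(int),
        observed=obs_a,
        expected=exp_a,
        n_merged=n_merged,
    )
    return HosmerLemeshowResult(statistic, df, p_value, table)


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _RISK_EPS, 1.0 - _RISK_EPS)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def lr_recalibration_test(sample: PredictionSample) -> LRRecalibrationResult:
    """Likelihood-ratio test of weak calibration (intercept 0, slope 1).

    Fits ``logit P(Y=1) = alpha + beta * logit(pi)`` by maximum likelihood
    (IRLS, deviance tolerance 1e-8, at most 100 iterations) and compares
    twice the log-likelihood against the fixed model ``(0, 1)``; the
    statistic is referred to chi-square with 2 df.
    """
    sample.require_both_classes()
    y = sample.outcomes
    z = logit(np.clip(sample.risks, _RISK_EPS, 1.0 - _RISK_EPS))
    exog = np.column_stack([np.ones_like(z), z])
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    model = sm.GLM(y, exog, family=sm.families.Binomial())
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            fit = model.fit(maxiter=100, tol=1e-8)
    except PerfectSeparationWarning:
        raise RuntimeError(
            "the data are completely separated on logit(risk); the "
            "recalibration maximum-likelihood estimate does not exist"
        ) from None
    except Exception as exc:  # pragma: no cover - statsmodels failure paths
        raise RuntimeError(f"logistic recalibration fit failed: {exc}") from exc
    if not getattr(fit, "converged", True):
        raise RuntimeError("logistic recalibration fit did not converge in 100 iterations")
    if np.max(np.abs(fit.params)) > 1e2:
        raise RuntimeError(
            "logistic recalibration fit diverged (|coefficient| > 100): "
            "the data are completely separated on logit(risk)"
        )
    ll_null = _bernoulli_loglik(y, sample.risks)
    lr = max(0.0, 2.0 * (float(fit.llf) - ll_null))
    p_value = float(chi2.sf(lr, 2))
    return LRRecalibrationResult(lr, 2, p_value, float(fit.params[0]), float(fit.params[1]))


def mean_calibration_ttest(sample: PredictionSample) -> tuple[float, float]:
    """Two-tailed one-sample t-test of the differences ``Y - pi`` against 0."""
    diffs = sample.outcomes - sample.risks
    if np.std(diffs) == 0.0:
        raise ValueError(
            "the differences Y - pi have zero variance; the t statistic is undefined"
        )
    t_stat, p_value = sps.ttest_1samp(diffs, 0.0)
    return float(t_stat), float(p_value)
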