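"""ROC and model-based ROC (mROC) curves as exact piecewise-linear objects.

The empirical ROC curve plots the true-positive fraction against the
false-positive fraction over all risk thresholds, built from the predicted
risks of event and non-event subjects.  The mROC curve is the ROC curve one
*should* observe if outcomes were Bernoulli draws from the predicted risks
themselves: the case CDF weights each subject by ``pi``, the control CDF by
``1 - pi``, so the curve depends on the predicted risks only, never on the
observed outcomes.  Under moderate calibration the two curves converge; the
integrated absolute difference between them is the ROC-equality statistic of
the calibration test in :mod:`mroc.calibration`.

Curves are stored as vertex lists with linear interpolation.  Tied predicted
risks collapse into a single vertex, so a tie group spanning both classes
appears as a diagonal segment; with this convention the all-tied curve is
exactly the chance line and the area under the empirical curve is the
tie-corrected Wilcoxon/Mann-Whitney statistic.  Vertex representation keeps
areas and curve differences exact (no grid discretisation anywhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sample import PredictionSample

__all__ = [
    "StepCurve",
    "empirical_roc",
    "mroc",
    "curve_auc",
    "model_based_cstat",
    "integrated_abs_diff",
]


@dataclass(frozen=True)
class StepCurve:
    """A monotone piecewise-linear curve from (0, 0) to (1, 1).

    ``fpr`` and ``tpr`` are the vertex coordinates; the curve is their
    linear interpolation.  Vertical risers appear as repeated ``fpr``
    values; diagonal segments arise from tied predicted risks.
    """

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        if fpr.ndim != 1 or fpr.shape != tpr.shape or fpr.shape[0] < 2:
            raise ValueError("fpr and tpr must be equal-length 1-d vectors (length >= 2)")
        for name, v in (("fpr", fpr), ("tpr", tpr)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(np.diff(v) < 0):
                raise ValueError(f"{name} must be nondecreasing")
        if fpr[0] != 0.0 or tpr[0] != 0.0 or fpr[-1] != 1.0 or tpr[-1] != 1.0:
            raise ValueError("curve must start at (0, 0) and end at (1, 1)")
        fpr.setflags(write=False)
        tpr.setflags(write=False)
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the interpolated curve at false-positive rate(s) ``t``.

        At a vertical riser (repeated fpr) the value returned is the upper
        limit; this is immaterial for any integral in ``t``.
        """
        return np.interp(t, self.fpr, self.tpr)

    @property
    def auc(self) -> float:
        return curve_auc(self)

    def to_tsv(self, path) -> None:
        """Write vertices as a two-column TSV (header ``fpr\\ttpr``).

        Uses shortest round-trip float representation so that
        :meth:`from_tsv` reproduces the curve bit-exactly.
        """
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for x, y in zip(self.fpr, self.tpr):
                fh.write(f"{float(x)!r}\t{float(y)!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "StepCurve":
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header != ["fpr", "tpr"]:
                raise ValueError(f"expected header 'fpr\\ttpr', got {header!r}")
            rows = [line.strip().split("\t") for line in fh if line.strip()]
        data = np.asarray(rows, dtype=float)
        return cls(data[:, 0], data[:, 1])


def _curve_from_weights(risks: np.ndarray, w1: np.ndarray, w0: np.ndarray) -> StepCurve:
    """Build an ROC-type curve from per-subject case/control weights.

    Thresholds run over the distinct risk values in descending order; the
    vertex after threshold ``v`` classifies exactly the subjects with
    ``risk >= v`` as positive.  Empirical ROC uses weights ``(Y, 1-Y)``;
    mROC uses ``(pi, 1-pi)``.
    """
    order = np.argsort(-risks, kind="stable")
    r = risks[order]
    first = np.empty(r.shape[0], dtype=bool)
    first[0] = True
    np.not_equal(r[1:], r[:-1], out=first[1:])
    starts = np.flatnonzero(first)
    g1 = np.add.reduceat(w1[order], starts)
    g0 = np.add.reduceat(w0[order], starts)
    W1 = g1.sum()
    W0 = g0.sum()
    if W1 <= 0.0 or W0 <= 0.0:
        raise ValueError("both weight totals must be positive to form a curve")
    tpr = np.concatenate(([0.0], np.cumsum(g1) / W1))
    fpr = np.concatenate(([0.0], np.cumsum(g0) / W0))
    # guard against rounding drift in the cumulative sums
    tpr[-1] = 1.0
    fpr[-1] = 1.0
    np.clip(tpr, 0.0, 1.0, out=tpr)
    np.clip(fpr, 0.0, 1.0, out=fpr)
    return StepCurve(fpr, tpr)


def empirical_roc(sample: PredictionSample) -> StepCurve:
    """Empirical ROC curve of predicted risks against observed outcomes.

    Vertices sit at each distinct predicted-risk threshold, with
    TP(t) = 1 - F1n(t) against FP(t) = 1 - F0n(t), where F1n and F0n are the
    empirical risk CDFs among events and non-events.  Requires both outcome
    classes.
    """
    sample.require_both_classes()
    return _curve_from_weights(sample.risks, sample.outcomes, 1.0 - sample.outcomes)


def mroc(risks: np.ndarray) -> StepCurve:
    """Model-based ROC curve from a vector of predicted risks.

    Uses the risk-weighted CDF estimators: each subject contributes weight
    ``pi_i`` to the case distribution and ``1 - pi_i`` to the control
    distribution.  The result depends only on the risks; observed outcomes
    never enter.  Requires ``0 < sum(pi) < n`` so both weight totals are
    positive (all-zero or all-one risks leave one distribution empty).
    """
    risks = np.asarray(risks, dtype=float)
    if risks.ndim != 1 or risks.shape[0] < 2:
        raise ValueError("need a 1-d vector of at least 2 predicted risks")
    if not np.all(np.isfinite(risks)) or risks.min() < 0.0 or risks.max() > 1.0:
        raise ValueError("predicted risks must lie in [0, 1]")
    s = risks.sum()
    if s <= 0.0 or s >= risks.shape[0]:
        raise ValueError(
            "mROC requires 0 < sum(risks) < n: with all risks 0 (or all 1) "
            "the model-implied case (control) distribution is empty"
        )
    return _curve_from_weights(risks, risks, 1.0 - risks)


def curve_auc(curve: StepCurve) -> float:
    """Exact trapezoid area under a piecewise-linear curve.

    For :func:`empirical_roc` output this equals the Mann-Whitney statistic
    with half credit for tied predictions; for :func:`mroc` output it equals
    the model-based c-statistic.
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def model_based_cstat(risks: np.ndarray) -> float:
    """Model-based c-statistic computed directly from pairwise weights.

    The probability that a case outranks a control when case/control labels
    are themselves drawn from the predicted risks: over all ordered subject
    pairs (i, j), pair (i, j) contributes concordance weight
    ``pi_i (1 - pi_j)`` if ``pi_i > pi_j`` and half that weight if the risks
    are tied, normalised by the total pairing weight
    ``(sum pi)(sum (1 - pi))``.  This pairwise form equals the area under
    the mROC curve exactly and serves as its independent oracle.

    Computed in O(n log n) with grouped prefix sums.
    """
    risks = np.asarray(risks, dtype=float)
    if risks.ndim != 1 or risks.shape[0] < 2:
        raise ValueError("need a 1-d vector of at least 2 predicted risks")
    if not np.all(np.isfinite(risks)) or risks.min() < 0.0 or risks.max() > 1.0:
        raise ValueError("predicted risks must lie in [0, 1]")
    r = np.sort(risks)
    first = np.empty(r.shape[0], dtype=bool)
    first[0] = True
    np.not_equal(r[1:], r[:-1], out=first[1:])
    starts = np.flatnonzero(first)
    if starts.shape[0] < 2:
        raise ValueError("fewer than 2 distinct risk values: no informative pairs")
    g_pi = np.add.reduceat(r, starts)          # sum of pi within each tie group
    g_q = np.add.reduceat(1.0 - r, starts)     # sum of 1 - pi within each tie group
    q_below = np.concatenate(([0.0], np.cumsum(g_q)[:-1]))
    num = float(np.sum(g_pi * q_below) + 0.5 * np.sum(g_pi * g_q))
    den = float(r.sum() * (1.0 - r).sum())
    if den <= 0.0:
        raise ValueError("degenerate risks: one pairing weight total is zero")
    return num / den


def _interval_abs_area(h: np.ndarray, d1: np.ndarray, d2: np.ndarray) -> float:
    """Sum of ∫|d(t)|dt over intervals where d is linear.

    ``d1``/``d2`` are the values of the (linear) difference at the interior
    quarter points of each interval of width ``h``; extrapolating gives the
    endpoint limits.  Where the sign changes inside an interval, the
    crossing point splits it into two exact triangles.
    """
    dl = 1.5 * d1 - 0.5 * d2
    dr = 1.5 * d2 - 0.5 * d1
    adl = np.abs(dl)
    adr = np.abs(dr)
    tot = adl + adr
    same = dl * dr >= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        crossed = np.where(tot > 0.0, (dl * dl + dr * dr) / np.where(tot > 0.0, tot, 1.0), 0.0)
    per = np.where(same, tot, crossed)
    return float(0.5 * np.sum(h * per))


def integrated_abs_diff(c1: StepCurve, c2: StepCurve) -> float:
    """Exact ``∫₀¹ |c1(t) − c2(t)| dt`` between two piecewise-linear curves.

    Evaluated on the union of both curves' fpr breakpoints; inside each
    union segment both curves are linear, and segments where the difference
    changes sign are split at the crossing point, so every piece is
    integrated exactly.  Symmetric in its arguments; zero iff the curves
    coincide as functions of the false-positive rate (vertical risers carry
    no width and cannot contribute).
    """
    xs = np.union1d(c1.fpr, c2.fpr)
    h = np.diff(xs)
    t1 = xs[:-1] + 0.25 * h
    t2 = xs[:-1] + 0.75 * h
    d1 = c1(t1) - c2(t1)
    d2 = c1(t2) - c2(t2)
    return _interval_abs_area(h, d1, d2)
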