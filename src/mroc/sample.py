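"""Validated container for predicted risks and observed binary outcomes.

External validation of a risk prediction model starts from one row per
subject: the model's predicted event probability ``pi*`` and the observed
outcome ``Y`` (1 = event, 0 = no event). :class:`PredictionSample` holds the
paired vectors and enforces the basic sanity constraints every downstream
statistic relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PredictionSample", "SingleClassError"]


class SingleClassError(ValueError):
    """Raised when an operation needs both outcome classes present."""


@dataclass(frozen=True)
class PredictionSample:
    """Paired predicted risks and observed binary outcomes for n subjects.

    Parameters
    ----------
    risks
        Predicted event probabilities, each in [0, 1].
    outcomes
        Observed outcomes, each exactly 0 or 1.

    Both vectors must have the same length n >= 2. Arrays are copied and
    frozen so a sample can be treated as an immutable value.
    """

    risks: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        risks = np.asarray(self.risks, dtype=float)
        outcomes = np.asarray(self.outcomes, dtype=float)
        if risks.ndim != 1 or outcomes.ndim != 1:
            raise ValueError("risks and outcomes must be one-dimensional")
        if risks.shape[0] != outcomes.shape[0]:
            raise ValueError(
                f"risks (n={risks.shape[0]}) and outcomes (n={outcomes.shape[0]}) "
                "must have equal length"
            )
        if risks.shape[0] < 2:
            raise ValueError("a prediction sample needs at least 2 subjects")
        if not np.all(np.isfinite(risks)):
            raise ValueError("risks contain non-finite values")
        if risks.min() < 0.0 or risks.max() > 1.0:
            bad = int(np.argmax((risks < 0) | (risks > 1)))
            raise ValueError(
                f"predicted risks must lie in [0, 1]; offending value "
                f"{risks[bad]!r} at position {bad}"
            )
        if not np.isin(outcomes, (0.0, 1.0)).all():
            bad = int(np.argmax(~np.isin(outcomes, (0.0, 1.0))))
            raise ValueError(
                f"outcomes must be exactly 0 or 1; offending value "
                f"{outcomes[bad]!r} at position {bad}"
            )
        risks.setflags(write=False)
        outcomes.setflags(write=False)
        object.__setattr__(self, "risks", risks)
        object.__setattr__(self, "outcomes", outcomes)

    @property
    def n(self) -> int:
        return int(self.risks.shape[0])

    @property
    def n_events(self) -> int:
        return int(self.outcomes.sum())

    @property
    def prevalence(self) -> float:
        return float(self.outcomes.mean())

    @property
    def mean_risk(self) -> float:
        return float(self.risks.mean())

    def require_both_classes(self) -> None:
        """Raise unless both events and non-events are observed.

        The empirical ROC curve (and hence any test of the null hypothesis
        that the model is calibrated) is undefined when every subject has
        the same outcome.
        """
        n1 = self.n_events
        if n1 == 0 or n1 == self.n:
            raise SingleClassError(
                "all observed outcomes are "
                f"{int(self.outcomes[0])}: the empirical ROC curve is "
                "undefined and the calibration null hypothesis is not "
                "testable without both outcome classes"
            )
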