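"""Synthetic validation samples and the replicated power study.

Three generator families, all built on a single standard-normal predictor X
with true risk ``p = expit(X)`` unless noted:

``linear``
    Miscalibrated predictions ``logit(pi*) = a + b * logit(p) = a + b * X``.
    The intercept ``a`` shifts mean calibration; the slope ``b`` tilts the
    calibration line.  With (a, b) = (0, 1) predictions are exactly the true
    risks.  Because miscalibration is linear on the logit scale, the
    logistic recalibration LR test is the theoretically optimal comparator
    in this family.

``nonlinear``
    ``logit(pi*) = a + b * sign(X) * |X|^(1/b)`` (b > 0).  The b-term is an
    odd function of X, so it bends the calibration curve (S-shaped
    miscalibration) while leaving the mean predicted risk untouched; only
    ``a`` moves mean calibration.

``casemix``
    External-validation populations for a fixed development model
    ``pi* = expit(X)``: the predictor has SD ``predictor_sd`` and the true
    association is ``P(Y=1) = expit(association_slope * X)``.  The four
    stylised panels are (sd, slope) in {(1,1), (0.5,1), (1,0.5),
    (0.5,0.5)}: shrinking the predictor SD changes the case mix (model
    stays calibrated), weakening the slope miscalibrates the model.

`run_power_study` replicates any set of scenarios, runs the five
calibration tests per replicate and tallies rejection fractions.  Seeding
is hierarchical: every (scenario, replicate) pair derives its own
independent stream from the master seed, so results are invariant to
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import expit
from scipy.stats import norm, rankdata

from .calibration import run_calibration_test
from .reference import hosmer_lemeshow_test, lr_recalibration_test
from .sample import PredictionSample

__all__ = [
    "ScenarioConfig",
    "PowerTable",
    "TEST_NAMES",
    "generate_sample",
    "gen_linear_scenario",
    "gen_nonlinear_scenario",
    "gen_casemix_population",
    "population_auc",
    "mean_predicted_risk",
    "run_power_study",
    "replicates_for_max_se",
    "empirical_auc",
]

TEST_NAMES = (
    "mean_calibration",
    "roc_equality",
    "unified",
    "hosmer_lemeshow",
    "likelihood_ratio",
)
_MC_TESTS = frozenset({"mean_calibration", "roc_equality", "unified"})


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic validation scenario.

    ``a`` (logit-scale intercept perturbation) and ``b`` (slope/shape) are
    used by the linear and nonlinear families; ``predictor_sd`` and
    ``association_slope`` by the casemix family.
    """

    family: str
    a: float = 0.0
    b: float = 1.0
    n: int = 1000
    predictor_sd: float = 1.0
    association_slope: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ("linear", "nonlinear", "casemix"):
            raise ValueError(f"unknown scenario family {self.family!r}")
        if self.n < 10:
            raise ValueError("scenario sample size must be at least 10")
        if self.predictor_sd <= 0:
            raise ValueError("predictor_sd must be positive")
        if self.family == "nonlinear" and self.b <= 0:
            raise ValueError("nonlinear family needs b > 0 (the exponent 1/b must exist)")

    def label(self) -> str:
        if self.family == "casemix":
            return f"casemix(sd={self.predictor_sd:g},slope={self.association_slope:g},n={self.n})"
        return f"{self.family}(a={self.a:g},b={self.b:g},n={self.n})"


def _resolve_rng(cfg: ScenarioConfig, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(cfg.seed)


def _prediction_transform(cfg: ScenarioConfig, x: np.ndarray) -> np.ndarray:
    if cfg.family == "linear":
        return expit(cfg.a + cfg.b * x)
    if cfg.family == "nonlinear":
        return expit(cfg.a + cfg.b * np.sign(x) * np.abs(x) ** (1.0 / cfg.b))
    return expit(x)  # casemix: the fixed development model


def _true_risk(cfg: ScenarioConfig, x: np.ndarray) -> np.ndarray:
    if cfg.family == "casemix":
        return expit(cfg.association_slope * x)
    return expit(x)


def _predictor_sd(cfg: ScenarioConfig) -> float:
    return cfg.predictor_sd if cfg.family == "casemix" else 1.0


def generate_sample(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> PredictionSample:
    """Draw one validation sample under the scenario's generative law."""
    rng = _resolve_rng(cfg, rng)
    x = rng.normal(0.0, _predictor_sd(cfg), cfg.n)
    y = (rng.random(cfg.n) < _true_risk(cfg, x)).astype(float)
    return PredictionSample(_prediction_transform(cfg, x), y)


def gen_linear_scenario(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> PredictionSample:
    """Sample with linear-on-the-logit miscalibration ``logit(pi*) = a + b X``."""
    if cfg.family != "linear":
        raise ValueError(f"expected a linear-family config, got {cfg.family!r}")
    return generate_sample(cfg, rng)


def gen_nonlinear_scenario(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> PredictionSample:
    """Sample with odd-function miscalibration ``logit(pi*) = a + b sign(X)|X|^(1/b)``."""
    if cfg.family != "nonlinear":
        raise ValueError(f"expected a nonlinear-family config, got {cfg.family!r}")
    return generate_sample(cfg, rng)


def gen_casemix_population(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> PredictionSample:
    """External-validation sample for the fixed model ``pi* = expit(X)``."""
    if cfg.family != "casemix":
        raise ValueError(f"expected a casemix-family config, got {cfg.family!r}")
    return generate_sample(cfg, rng)


def empirical_auc(risks: np.ndarray, outcomes: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie correction, in O(n log n)."""
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes)
    n1 = int(outcomes.sum())
    n0 = outcomes.shape[0] - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("empirical AUC needs both outcome classes")
    ranks = rankdata(risks)
    return float((ranks[outcomes == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def population_auc(cfg: ScenarioConfig, method: str = "simulation") -> float:
    """Population AUC of the scenario's predictions against its outcomes.

    ``simulation`` draws max(cfg.n, 10^6) subjects (Monte-Carlo SE about
    0.0005) and computes the empirical AUC.  ``quadrature`` integrates the
    case and control predictor densities on a dense 1-D grid: predictions
    are monotone increasing in X in every family (b > 0), so the AUC equals
    P(X_case > X_control) = ∫ f1(x) F0(x) dx.  The two routes agree to
    three decimals.
    """
    if method == "simulation":
        sim_cfg = replace(cfg, n=max(cfg.n, 1_000_000))
        sample = generate_sample(sim_cfg)
        return empirical_auc(sample.risks, sample.outcomes)
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}; use 'simulation' or 'quadrature'")
    sd = _predictor_sd(cfg)
    if cfg.family != "casemix" and cfg.b == 0.0:
        return 0.5  # constant predictions: every pair is tied
    x = np.linspace(-12.0 * sd, 12.0 * sd, 240_001)
    phi = norm.pdf(x, 0.0, sd)
    p = _true_risk(cfg, x)
    f1 = phi * p
    f0 = phi * (1.0 - p)
    i1 = np.trapezoid(f1, x)
    i0 = np.trapezoid(f0, x)
    if i1 <= 0.0 or i0 <= 0.0:
        return 0.5
    F0 = integrate.cumulative_trapezoid(f0, x, initial=0.0) / i0
    return float(np.trapezoid(f1 / i1 * F0, x))


def mean_predicted_risk(cfg: ScenarioConfig) -> float:
    """``E[pi*]`` under the scenario, by adaptive quadrature split at 0.

    The split handles the ``sign(X)`` kink of the nonlinear family exactly
    at the origin.
    """
    sd = _predictor_sd(cfg)

    def integrand(x: float) -> float:
        xv = np.asarray([x])
        return float(norm.pdf(x, 0.0, sd) * _prediction_transform(cfg, xv)[0])

    lo, _ = integrate.quad(integrand, -np.inf, 0.0)
    hi, _ = integrate.quad(integrand, 0.0, np.inf)
    return lo + hi


@dataclass(frozen=True)
class PowerTable:
    """Rejection proportions per (scenario, test) from a replicated study."""

    table: pd.DataFrame

    @classmethod
    def empty(cls) -> "PowerTable":
        return cls(pd.DataFrame(
            columns=["scenario", "test", "replicates", "rejections", "power", "mc_se"]
        ))

    def power(self, scenario_label: str, test: str) -> float:
        df = self.table
        row = df[(df["scenario"] == scenario_label) & (df["test"] == test)]
        if row.empty:
            raise KeyError(f"no row for ({scenario_label!r}, {test!r})")
        return float(row["power"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        text = self.table.to_json(orient="records", indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _pvalues_for_sample(
    sample: PredictionSample, tests: Sequence[str], M_null: int, null_seed: int
) -> dict[str, float]:
    out: dict[str, float] = {}
    if _MC_TESTS.intersection(tests):
        res = run_calibration_test(sample, M=M_null, seed=null_seed)
        out["mean_calibration"] = res.p_a
        out["roc_equality"] = res.p_b
        out["unified"] = res.p_unified
    if "hosmer_lemeshow" in tests:
        out["hosmer_lemeshow"] = hosmer_lemeshow_test(sample).p_value
    if "likelihood_ratio" in tests:
        out["likelihood_ratio"] = lr_recalibration_test(sample).p_value
    return out


def run_power_study(
    scenarios: Iterable[ScenarioConfig],
    tests: Sequence[str] = TEST_NAMES,
    replicates: int = 500,
    alpha: float = 0.05,
    M_null: int = 2000,
    seed: int = 0,
) -> PowerTable:
    """Estimate rejection probabilities of the requested tests per scenario.

    For every scenario x replicate a fresh validation sample is generated
    and each test is run at level ``alpha`` (reject when p <= alpha).
    Each (scenario, replicate) pair derives independent data and
    null-simulation streams from the master ``seed``, so the table is fully
    reproducible and order-independent.  Monte-Carlo SE is
    ``sqrt(p(1-p)/replicates)``.
    """
    scenarios = list(scenarios)
    tests = list(tests)
    unknown = [t for t in tests if t not in TEST_NAMES]
    if unknown:
        raise ValueError(f"unknown test name(s) {unknown!r}; choose from {TEST_NAMES}")
    if scenarios and replicates < 100:
        raise ValueError("need at least 100 replicates for a power estimate")
    rows = []
    for si, cfg in enumerate(scenarios):
        rejections = {t: 0 for t in tests}
        for j in range(replicates):
            data_rng = np.random.default_rng(np.random.SeedSequence([seed, si, j, 0]))
            null_seed = int(
                np.random.SeedSequence([seed, si, j, 1]).generate_state(1)[0] % (2**31)
            )
            sample = generate_sample(cfg, data_rng)
            pvals = _pvalues_for_sample(sample, tests, M_null, null_seed)
            for t in tests:
                if pvals[t] <= alpha:
                    rejections[t] += 1
        for t in tests:
            p_hat = rejections[t] / replicates
            rows.append({
                "scenario": cfg.label(),
                "test": t,
                "replicates": replicates,
                "rejections": rejections[t],
                "power": p_hat,
                "mc_se": float(np.sqrt(p_hat * (1.0 - p_hat) / replicates)),
            })
    if not rows:
        return PowerTable.empty()
    return PowerTable(pd.DataFrame(rows))


def replicates_for_max_se(se: float, p: float = 0.5) -> int:
    """Smallest replicate count with SE of a rejection proportion <= ``se``.

    Worst case is p = 1/2: SE = sqrt(p(1-p)/R) <= se gives
    R = ceil(p(1-p)/se^2); at se = 0.01 this is the classic 2,500.
    """
    if not (0.0 < se < 1.0) or not (0.0 < p < 1.0):
        raise ValueError("need 0 < se < 1 and 0 < p < 1")
    return int(np.ceil(p * (1.0 - p) / (se * se)))
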