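"""How case mix and miscalibration move the ROC curve - and how mROC tells
them apart.

A risk model pi* = expit(X) is developed where X ~ Normal(0, 1) and the
true association is P(Y=1) = expit(X).  We then validate it in four
populations: (A) identical to development, (B) underdispersed predictor
(calibrated, different case mix), (C) weaker association (miscalibrated,
same case mix), (D) both at once.

The printed AUC drops in B, C and D alike - the ROC curve alone cannot say
why.  The mROC gap (Bn) can: it stays near zero whenever the model is
calibrated (A, B) and is clearly positive under miscalibration (C, D).
"""

import numpy as np

from mroc import (
    PredictionSample,
    ScenarioConfig,
    curve_auc,
    empirical_roc,
    gen_casemix_population,
    mroc,
    roc_equality_stat,
)

PANELS = {
    "A (same population)": (1.0, 1.0),
    "B (underdispersed predictor)": (0.5, 1.0),
    "C (weaker association)": (1.0, 0.5),
    "D (both)": (0.5, 0.5),
}

print(f"{'panel':32s} {'AUC':>6s} {'mAUC':>6s} {'Bn gap':>7s}  calibrated?")
for name, (sd, slope) in PANELS.items():
    cfg = ScenarioConfig(family="casemix", predictor_sd=sd, association_slope=slope,
                         n=100_000, seed=1)
    sample = gen_casemix_population(cfg)
    auc = curve_auc(empirical_roc(sample))
    mauc = curve_auc(mroc(sample.risks))
    gap = roc_equality_stat(sample)
    print(f"{name:32s} {auc:6.3f} {mauc:6.3f} {gap:7.4f}  "
          f"{'yes' if slope == 1.0 else 'no'}")

print()
print("Reading the table: mAUC is the AUC the model *should* achieve given")
print("this population's case mix.  In B the AUC drop is fully explained by")
print("case mix (AUC ~ mAUC, tiny gap); in C the mAUC stays at the")
print("development value, so the entire AUC drop is miscalibration.")
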