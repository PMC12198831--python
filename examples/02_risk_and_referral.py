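"""Score a cohort with the Cox-form risk model and compare referral rules.

Calibrates the (stand-in) risk model so the cohort mean 1-year CRC risk is
1.2%, then contrasts FIT-threshold and risk-threshold referral on referral
volume and classification performance against the allocated CRC truth.
"""

import numpy as np

import crctriage as ct
from crctriage.pipeline import ModelBundle, prepare_cohort

cohort = prepare_cohort(ModelBundle.default(), n=100_000, seed=2)
pop = cohort.population
print(f"calibrated mean 1-year CRC risk: {cohort.risks.mean():.4%}")
print(f"baseline CRC prevalence:         {cohort.baseline_states.has_crc.mean():.4%}\n")

crc_flags = cohort.baseline_states.has_crc
for strategy in (
    ct.Strategy(ct.StrategyKind.FIT, 10.0),
    ct.Strategy(ct.StrategyKind.COX_RISK, 0.0064),
    ct.Strategy(ct.StrategyKind.COX_RISK, 0.012),
):
    perf = ct.performance_summary(pop, strategy, crc_flags, cohort.cox_model)
    print(
        f"{strategy.label:16s} referrals {perf['referrals']:7d}  "
        f"sensitivity {perf['sensitivity']:.3f}  PPV {perf['ppv']:.4f}"
    )
# The risk score concentrates referrals on high-risk (older, anaemic,
# high-FIT) patients: matched sensitivity is reached with fewer referrals
# than a FIT-only threshold.
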