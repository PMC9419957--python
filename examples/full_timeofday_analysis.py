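"""Run the complete time-of-day analysis on a desk-scale synthetic cohort.

A cohort with a model-7 morning effect on the hemodynamic decay parameter is
simulated, every subject-session is inverted, and the hierarchical empirical
Bayes + Bayesian model comparison is run twice: over the connectivity block
and over the hemodynamic block.  The expected picture mirrors the scientific
claim the package exists to probe: the hemodynamic analysis should detect a
morning model, the connectivity analysis should stay with the null model.
"""

import numpy as np

from chronodcm import CohortConfig, PipelineConfig, run_pipeline
from chronodcm.pipeline import render_connectivity_matrix

config = PipelineConfig(
    cohort=CohortConfig(
        n_rois=4,
        n_subjects_per_timespan=32,
        n_volumes=400,
        effect_model_id=7,
        effect_targets=("decay",),
        effect_size=0.1,
        between_subject_sd=0.1,
        seed=1,
    )
)
report = run_pipeline(config)

print(f"{report.n_records} subject-sessions, {report.n_converged} converged "
      f"({report.timings})")
for label, analysis in (("connectivity", report.connectivity),
                        ("hemodynamic", report.hemodynamic)):
    probs = analysis.bmc.posterior_probs
    top = np.argsort(-probs)[:3]
    print(f"\n{label} analysis: winning model {analysis.winning_id}")
    for m in top:
        print(f"  model {m + 1:2d}: posterior probability {probs[m]:.3f}")
print("\nhemodynamic effect sizes (Cohen's d):", {
    k: round(v, 3) for k, v in report.hemodynamic.effect_sizes.items()
})
print("\nmean effective connectivity (Hz, from columns to rows, pp>0.95):")
print(render_connectivity_matrix(report.connectivity.bma, 0.95))
# Model 18 is the null (no time-of-day) model; model 7 predicts a deviation
# during the two morning timespans.  The diagonal shows self-inhibition
# rates near the -0.5 Hz reference.
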