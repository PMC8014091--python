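"""Reference-peptide drift correction on a simulated 50-injection run.

Peak areas decay linearly across the injection sequence. The spiked
reference peptides at the 0.01x dilution level estimate the drift; each
injection's peptide areas are multiplied by the reciprocal of its mean
reference intensity ratio, which flattens the drift line exactly and
shrinks the reference coefficient of variation.
"""

import prmnet
from prmnet import normalize, quant

cfg = prmnet.SimulationConfig()
cohort = prmnet.generate_cohort(cfg)
targets = prmnet.generate_target_list(cfg)
table, ref_areas, truth = prmnet.generate_transitions(cohort, targets, cfg)

peptides = quant.quantify_peptides(table)
panel = normalize.build_reference_panel(peptides, targets)
normalize.select_reference_peptides(panel)
qc = normalize.qc_report(panel)

print(f"drift fit: slope {qc['drift_slope']:.4f}, "
      f"intercept {qc['drift_intercept']:.3f}, R^2 {qc['drift_r_squared']:.3f}")
print(f"reference CV before correction: {qc['cv_pre_percent']:.2f}%")
print(f"reference CV after correction:  {qc['cv_post_percent']:.2f}%")
print(f"refit slope after correction:   {qc['post_correction_slope']:.1e}")

# The fitted slope/intercept recover the planted drift line (-0.0167,
# 1.417) up to measurement noise; the refit slope after correction is
# zero by construction, and the CV roughly halves.
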