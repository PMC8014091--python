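"""Generate the synthetic study: cohort, target list and transition data.

The default design mirrors a 44-case postmortem cohort (12 control,
8 asymptomatic AD, 12 AD, 12 PD) measured by targeted PRM on 870 peptides
rolling up to 390 entities, with six pooled-standard injections
interleaved among the 50 runs.
"""

import prmnet

cfg = prmnet.SimulationConfig()
cohort = prmnet.generate_cohort(cfg)
targets = prmnet.generate_target_list(cfg)
table, ref_areas, truth = prmnet.generate_transitions(cohort, targets, cfg)

print("cases per group: ", cohort["group"].value_counts().to_dict())
print("age at death (AD):", round(cohort.loc[cohort.group == "AD", "age_death"].mean(), 1))
endo = targets[~targets.is_reference]
print("peptides:", len(endo), " entities:", endo["entity"].nunique())
print("MAPT peptides:", (endo.protein == "MAPT").sum(),
      " APP peptides:", (endo.protein == "APP").sum())
print("transition rows:", len(table))
print("planted modules:", len(truth["module_sizes"]),
      " sizes:", truth["module_sizes"][:6], "...")

# Each case's entities were planted with module structure and disease
# shifts; the truth dictionary carries the labels every later stage is
# benchmarked against.
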