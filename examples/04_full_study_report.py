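"""Run the complete study pipeline on a reference-sized synthetic cohort.

25 subjects / 50 eyes (30 healthy, ~10 glaucoma-suspect, ~10 preperimetric
glaucoma), split 30/20 into training and validation eyes; fits both mixed
models, runs ANOVA + Games-Howell + Welch + ROC, and prints the report.
"""

from rgcest import StudyConfig, SyntheticConfig, generate_cohort, run_study

cohort = generate_cohort(SyntheticConfig(seed=42))
report = run_study(cohort, StudyConfig(seed=42))
print(report.to_markdown())
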