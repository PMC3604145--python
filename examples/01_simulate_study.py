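"""Simulate the paired supplementation study.

Builds the 8-subject cohort (two dose arms, 4 deficient / 4
insufficient-sufficient at baseline) and a 20,000-gene log2 expression
matrix with 291 planted supplementation-responsive genes (209 up, 82
down), then prints the cohort and the matrix dimensions.
"""

from vdresponse import default_study_cohort, gen_expression
from vdresponse.synthetic import cohort_frame, default_supplementation_design

cohort = default_study_cohort(seed=1)
print(cohort_frame(cohort).to_string())
# serum_baseline < 20 ng/ml defines the deficient status class

design = default_supplementation_design(seed=1)
matrix, truth = gen_expression(cohort, design)
print(f"\nexpression matrix: {matrix.n_genes} genes x {matrix.n_samples} samples")
print(f"planted responsive genes: {len(truth)} "
      f"({(truth['direction'] == 'up').sum()} up, "
      f"{(truth['direction'] == 'down').sum()} down)")
# each planted gene shifts its follow-up values by a log2 fold change
# drawn from [0.7, 4.7]; everything else is pure noise (SD 0.1 log2)
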