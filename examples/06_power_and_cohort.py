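"""Design statistics: sample size and cohort arithmetic.

Reproduces the per-group N from the study design parameters and the
serum 25(OH)D changes from the packaged demographics table.
"""

from vdresponse import PowerSpec, cohort_summary, load_fixture, sample_size
from vdresponse.cohort_stats import delta_sweep

spec = PowerSpec(alpha=0.05, power=0.80, sd=1.0, delta=2.0)
print(f"N per group (alpha=0.05, power=80%, sd=1, delta=2): {sample_size(spec)}")
# the normal-approximation formula gives N = 4 per group

print("\nN over the 1.5..3 detectable-change sweep:")
print(delta_sweep(spec, [1.5, 2.0, 2.5, 3.0]).to_string(index=False))

summary = cohort_summary(load_fixture("table1"))
print(f"\npooled mean age: {summary['mean_age']:.1f} y")
print(f"serum change, 400 IU arm:  {summary['serum_change_400']:.1f} ng/ml")
print(f"serum change, 2000 IU arm: {summary['serum_change_2000']:.1f} ng/ml")
# the 2000 IU arm's mean increase is about twice the 400 IU arm's
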