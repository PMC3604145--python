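"""qPCR verification: delta-delta-Ct and microarray concordance.

Computes relative expression from Ct values against an endogenous
control (18S rRNA) and regresses qPCR log2 ratios on microarray log2
fold changes with a 95% prediction interval.
"""

import numpy as np
import pandas as pd

from vdresponse import concordance_fit, ddct_relative_expression

qpcr = pd.DataFrame(
    {
        "gene_id": ["CD83"] * 2 + ["TNFAIP3"] * 2,
        "sample_id": ["b1", "f1", "b2", "f2"],
        "condition": ["baseline", "followup"] * 2,
        "ct_target": [22.0, 23.0, 25.0, 25.6],
        "ct_control": [15.0, 15.0, 15.0, 15.0],
    }
)
rq = ddct_relative_expression(qpcr, reference_condition="baseline")
print(rq[["gene_id", "condition", "rq"]].to_string(index=False))
# one extra cycle to threshold (CD83) means half the transcript: rq 0.5

microarray_fc = np.array([-1.0, -0.6, 0.8, 1.4])
qpcr_fc = np.array([-1.1, -0.5, 0.7, 1.5])
fit = concordance_fit(microarray_fc, qpcr_fc)
print(f"\nconcordance: slope {fit.slope:.2f}, intercept {fit.intercept:.2f}, "
      f"r {fit.r:.3f}")
print(f"95% prediction half-width at x=0: {fit.halfwidth(0.0):.2f} log2 units")
# slope near 1 and high r mean the qPCR changes track the microarray
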