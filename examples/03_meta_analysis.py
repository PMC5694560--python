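"""Cluster projected QTLs into meta-QTLs and pool their confidence intervals.

Two true loci at 25 and 80 cM are each detected by four populations with
noisy peaks and ~10 cM confidence intervals.  The meta-analysis selects the
number of clusters by penalised maximum likelihood and pools each cluster's
CI, which shrinks roughly with the square root of the member count.
"""

import numpy as np

from mqtlkit import run_meta_analysis
from mqtlkit.qtl import ProjectedQTL, QTLRecord

rng = np.random.default_rng(7)
projected = []
for t, mu in enumerate([25.0, 80.0]):
    for j in range(4):
        x = float(rng.normal(mu, 1.5))
        rec = QTLRecord(
            qtl_id=f"q{t}{j}", population_id=f"pop{j}", trait_class="GY",
            trait_component=["TKW", "GrN"][t], chromosome="2B",
            peak=x, ci_left=x - 5.0, ci_right=x + 5.0,
        )
        projected.append(ProjectedQTL(rec, source_map="study"))

result = run_meta_analysis(projected, criterion="awe")
print(result.report_frame().to_string(index=False))
# Each MQTL's pooled 95% CI half-width is 1.96/sqrt(sum 1/s_i^2) ~ 2.5 cM
# here, versus ~5 cM for a single member QTL: co-location across independent
# populations is what narrows the interval.
print("\naudit:")
print(result.audit.to_string(index=False))
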