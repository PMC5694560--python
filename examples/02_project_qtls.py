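"""Project one study's QTLs onto a consensus map through shared markers.

A study map that is a half-scale version of the consensus doubles every
projected position; confidence-interval containment is preserved because the
homothetic projection is monotone.
"""

import pandas as pd

from mqtlkit import GeneticMap, project_qtl_table
from mqtlkit.qtl import QTLRecord

consensus = GeneticMap(
    "consensus",
    pd.DataFrame(
        {
            "chromosome": "1A",
            "marker": ["m1", "m2", "m3", "m4"],
            "position_cM": [0.0, 30.0, 60.0, 90.0],
            "marker_type": "SNP",
        }
    ),
)
study_map = GeneticMap(
    "study",
    pd.DataFrame(
        {
            "chromosome": "1A",
            "marker": ["m1", "m2", "m3", "m4"],
            "position_cM": [0.0, 15.0, 30.0, 45.0],  # half-scale coordinates
            "marker_type": "SNP",
        }
    ),
)
qtls = [
    QTLRecord("q1", "pop1", "GY", "TKW", "1A", peak=10.0, ci_left=5.0, ci_right=15.0),
    QTLRecord("q2", "pop1", "GPC", "GPC", "1A", peak=40.0, ci_left=35.0, ci_right=44.0),
    QTLRecord("q3", "pop1", "GY", "GrN", "1A", peak=20.0),  # no published CI
]

result = project_qtl_table(qtls, study_map, consensus)
for p in result.projected:
    print(
        f"{p.qtl_id}: peak {p.peak:.2f} cM, CI [{p.ci_left:.2f}, {p.ci_right:.2f}]"
        f"  flags={sorted(p.flags) or '-'}"
    )
# q1/q2 double their coordinates; q3 had no CI, so a default 20 cM interval
# was imputed around its peak before projection (flag imputed_ci).
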