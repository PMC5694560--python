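"""Serialisation of MQTL reports (Table-3-style layout)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

REPORT_COLUMNS = [
    "mqtl_id", "trait_class", "chromosome", "ci_left", "ci_right",
    "width_cM", "n_qtls", "n_populations", "components", "member_qtl_ids",
]


def round2(x: float) -> float:
    """Round half away from zero to 2 decimals (serialisation only)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def mqtl_report_frame(mqtls) -> pd.DataFrame:
    rows = []
    for m in mqtls:
        rows.append(
            {
                "mqtl_id": m.mqtl_id,
                "trait_class": m.trait_class,
                "chromosome": m.chromosome,
                "ci_left": round2(m.ci_left),
                "ci_right": round2(m.ci_right),
                "width_cM": round2(m.ci_right - m.ci_left),
                "n_qtls": len(m.member_qtls),
                "n_populations": m.n_populations,
                "components": ", ".join(m.components),
                "member_qtl_ids": ";".join(m.member_qtls),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_mqtl_report(mqtls, path) -> pd.DataFrame:
    """Write the tab-separated MQTL report; returns the frame written."""
    frame = mqtl_report_frame(mqtls)
    out = frame.copy()
    for col in ("ci_left", "ci_right", "width_cM"):
        out[col] = out[col].map(lambda v: f"{v:.2f}")
    out.to_csv(path, sep="\t", index=False)
    return frame
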