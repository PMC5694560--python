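"""Packaged reference tables from the wheat integration study.

Three small TSVs transcribe the study's printed summary tables (decimal
commas normalised to dots):

- ``table1_markers.tsv`` — per-chromosome marker counts of the consensus
  map by marker type (21 wheat chromosomes x SNP/SSR/RFLP/DarT/Gene);
- ``table2_qtl_counts.tsv`` — the 27 mapping populations with their
  per-trait-component QTL counts (grain yield, baking quality, grain
  protein content);
- ``table3_mqtl.tsv`` — the 32 published meta-QTLs with confidence
  intervals, member counts and proposed candidate genes.

Note: the published table's B-subgenome total (55,524) disagrees by one
with the sum of its own rows (55,525); derived sums here are always
computed from the per-chromosome rows.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .maps import GeneticMap

GY_COMPONENTS = ("Th", "TKW", "Tn", "GrN", "HI", "PH", "SL", "GrW")
BQ_COMPONENTS = ("Visco", "W", "Vol", "OtherBQ")
GPC_COMPONENTS = ("GPC",)


def _load(name: str) -> pd.DataFrame:
    with resources.files("mqtlkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def table1_marker_counts() -> pd.DataFrame:
    """Per-chromosome x marker-type counts of the published consensus map."""
    return _load("table1_markers.tsv")


def table1_as_map() -> GeneticMap:
    """Expand the Table-1 counts into a synthetic placeholder map.

    One marker per counted unit, with arbitrary evenly spaced positions:
    only counts (not positions) are meaningful, which is exactly what the
    summary operations consume.
    """
    counts = table1_marker_counts()
    chroms, names, types = [], [], []
    for _, row in counts.iterrows():
        chrom = row["chromosome"]
        i = 0
        for mtype in ("SNP", "SSR", "RFLP", "DarT", "Gene"):
            for _ in range(int(row[mtype])):
                chroms.append(chrom)
                names.append(f"{chrom}_{mtype}_{i:06d}")
                types.append(mtype)
                i += 1
    frame = pd.DataFrame(
        {
            "chromosome": chroms,
            "marker": names,
            "position_cM": [0.01 * i for i in range(len(names))],
            "marker_type": types,
        }
    )
    return GeneticMap("table1", frame)


def table2_populations() -> pd.DataFrame:
    """The 27 mapping populations with per-component QTL counts."""
    return _load("table2_qtl_counts.tsv")


def table2_as_qtl_frame() -> pd.DataFrame:
    """Expand the per-population counts into one QTL row per counted QTL.

    Positions are placeholders (peak 10.0, CI [5, 15] on chromosome "1A");
    only ids, populations, trait classes and components are meaningful.
    """
    pops = table2_populations()
    rows = []
    for _, row in pops.iterrows():
        for comp in GY_COMPONENTS + BQ_COMPONENTS + GPC_COMPONENTS:
            if comp in GY_COMPONENTS:
                trait = "GY"
            elif comp in BQ_COMPONENTS:
                trait = "BQ"
            else:
                trait = "GPC"
            for k in range(int(row[comp])):
                rows.append(
                    {
                        "qtl_id": f"{row['population_id']}_{comp}_{k}",
                        "population_id": row["population_id"],
                        "trait_class": trait,
                        "trait_component": comp,
                        "chromosome": "1A",
                        "peak_cM": 10.0,
                        "ci_left_cM": 5.0,
                        "ci_right_cM": 15.0,
                        "lod": "",
                        "r2": "",
                    }
                )
    return pd.DataFrame(rows)


def table3_mqtls() -> pd.DataFrame:
    """The 32 published meta-QTLs (candidate_genes semicolon-joined)."""
    frame = _load("table3_mqtl.tsv")
    frame["candidate_genes"] = frame["candidate_genes"].fillna("")
    return frame


def table3_candidate_genes() -> list[str]:
    """Flat list of the proposed candidate genes (37 entries)."""
    out: list[str] = []
    for cell in table3_mqtls()["candidate_genes"]:
        out.extend(g for g in str(cell).split(";") if g)
    return out
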