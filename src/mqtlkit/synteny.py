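"""Syntenome anchoring, MQTL gene repertoires and CIP/CALP candidate scoring.

The *syntenome* is an ordered gene list along chromosomes (order inferred
from synteny with related grass genomes), anchored to the consensus genetic
map through backbone markers that carry both a consensus cM position and an
ordinal slot in the gene order.  Genes under any MQTL confidence interval
can then be extracted directly.

Candidate genes are scored from BLAST tabular (outfmt 6) output with two
cumulative-alignment statistics over the retained HSPs of a query-subject
pair:

- CIP, cumulative identity percentage: summed identical positions over
  summed aligned columns, x100;
- CALP, cumulative alignment length percentage: summed aligned columns over
  the query length, x100 (capped at 100).

HSPs are made non-redundant greedily by descending bitscore; an HSP whose
query span overlaps already-accepted coverage by more than 5% of its own
span is discarded, so uncontrolled HSP stacking cannot inflate CALP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

HSP_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "query_start", "query_end",
    "subject_start", "subject_end", "evalue", "bitscore",
]

SYNTENOME_COLUMNS = ["chromosome", "ordinal", "gene_id", "orthologs", "scaffold"]
BACKBONE_COLUMNS = ["chromosome", "ordinal", "marker", "consensus_cM"]

#: Maximum fraction of an HSP's own query span that may overlap
#: already-accepted coverage before the HSP is discarded.
OVERLAP_TOLERANCE = 0.05


# ---------------------------------------------------------------------------
# Syntenome anchoring
# ---------------------------------------------------------------------------


def read_syntenome(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "gene_id": str})
    missing = [c for c in SYNTENOME_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing syntenome columns {missing}")
    for c in ("orthologs", "scaffold"):
        if c not in frame.columns:
            frame[c] = ""
    frame["orthologs"] = frame["orthologs"].fillna("")
    frame["scaffold"] = frame["scaffold"].fillna("")
    return frame[SYNTENOME_COLUMNS]


def read_backbone(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "marker": str})
    missing = [c for c in BACKBONE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing backbone columns {missing}")
    return frame[BACKBONE_COLUMNS]


def anchor_syntenome(genes: pd.DataFrame, backbone: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene an ``anchored_cM`` by ordinal interpolation.

    Within each chromosome the gene's cM is linearly interpolated *in
    ordinal rank* between the flanking backbone markers; genes outside the
    terminal markers extend the terminal interval's cM-per-ordinal rate.
    Chromosomes with fewer than two backbone markers are left unanchored
    (anchored_cM = NaN).  Gene ordinals must be strictly increasing per
    chromosome; anchored_cM is then non-decreasing with ordinal.
    """
    out = genes.copy()
    out["anchored_cM"] = np.nan
    for chrom, sub in genes.groupby("chromosome"):
        ords = sub["ordinal"].to_numpy(float)
        if np.any(np.diff(ords[np.argsort(ords)]) <= 0) or len(set(ords)) != len(ords):
            raise ValidationError(f"chromosome {chrom!r}: gene ordinals not strictly increasing")
        bb = backbone[backbone["chromosome"] == chrom].sort_values("ordinal")
        if len(bb) < 2:
            continue
        bx = bb["ordinal"].to_numpy(float)
        by = bb["consensus_cM"].to_numpy(float)
        vals = np.interp(ords, bx, by)
        lo = ords < bx[0]
        if lo.any():
            rate = (by[1] - by[0]) / (bx[1] - bx[0])
            vals[lo] = by[0] + (ords[lo] - bx[0]) * rate
        hi = ords > bx[-1]
        if hi.any():
            rate = (by[-1] - by[-2]) / (bx[-1] - bx[-2])
            vals[hi] = by[-1] + (ords[hi] - bx[-1]) * rate
        out.loc[sub.index, "anchored_cM"] = np.maximum(vals, 0.0)
    return out


def genes_in_interval(
    anchored: pd.DataFrame, chromosome: str, interval: tuple[float, float]
) -> pd.DataFrame:
    """Genes whose anchored_cM lies in the closed cM interval, in ordinal order."""
    left, right = interval
    if left > right:
        raise ValidationError(f"interval left {left} > right {right}")
    if chromosome not in set(anchored["chromosome"]):
        raise ValidationError(f"unknown chromosome {chromosome!r}")
    sub = anchored[anchored["chromosome"] == chromosome]
    hit = sub[(sub["anchored_cM"] >= left) & (sub["anchored_cM"] <= right)]
    return hit.sort_values("ordinal").reset_index(drop=True)


# ---------------------------------------------------------------------------
# HSPs and CIP/CALP
# ---------------------------------------------------------------------------


def read_hsps(path) -> pd.DataFrame:
    """Read BLAST tabular (outfmt-6-style, 12 columns, headerless) HSPs."""
    frame = pd.read_csv(path, sep="\t", header=None, names=HSP_COLUMNS)
    bad = frame[frame["query_start"] > frame["query_end"]]
    if len(bad):
        raise ValidationError(
            f"{path}: query_start > query_end for {bad['query_id'].iloc[0]!r}"
        )
    return frame


def merge_hsps(hsps: pd.DataFrame) -> pd.DataFrame:
    """Non-redundant HSP subset for one query-subject pair.

    HSPs are accepted greedily in descending bitscore (ties broken by longer
    alignment, then smaller query_start); an HSP overlapping already-accepted
    query coverage by more than OVERLAP_TOLERANCE of its own span is
    discarded.  Coordinates are 1-based inclusive.
    """
    if len(hsps) == 0:
        return hsps
    if hsps["query_id"].nunique() > 1 or hsps["subject_id"].nunique() > 1:
        raise ValidationError("merge_hsps expects HSPs of a single query-subject pair")
    order = hsps.sort_values(
        ["bitscore", "alignment_length", "query_start"],
        ascending=[False, False, True],
        kind="stable",
    )
    covered: list[tuple[int, int]] = []  # disjoint accepted query intervals
    kept = []
    for idx, r in order.iterrows():
        a, b = int(r["query_start"]), int(r["query_end"])
        span = b - a + 1
        overlap = sum(
            max(0, min(b, d) - max(a, c) + 1) for c, d in covered
        )
        if overlap > OVERLAP_TOLERANCE * span:
            continue
        kept.append(idx)
        covered.append((a, b))
        covered.sort()
        merged = [covered[0]]
        for c, d in covered[1:]:
            if c <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], d))
            else:
                merged.append((c, d))
        covered = merged
    return hsps.loc[sorted(kept)]


@dataclass(frozen=True)
class CandidateHit:
    query_id: str
    subject_id: str
    cip: float
    calp: float
    n_hsps_used: int


def compute_cip_calp(hsps: pd.DataFrame, query_length: int) -> CandidateHit:
    """CIP and CALP over a merged HSP set.

    AL = sum of alignment lengths; identities = sum(pident/100 * length);
    CIP = 100 * identities / AL; CALP = 100 * AL / query_length, capped at
    100 so it stays interpretable as a coverage percentage.
    """
    if query_length <= 0:
        raise ValidationError(f"query_length must be > 0 (got {query_length})")
    if len(hsps) == 0:
        raise ValidationError("compute_cip_calp: empty HSP set (no hit)")
    al = float(hsps["alignment_length"].sum())
    identities = float((hsps["percent_identity"] / 100.0 * hsps["alignment_length"]).sum())
    cip = 100.0 * identities / al
    calp = min(100.0 * al / query_length, 100.0)
    return CandidateHit(
        query_id=str(hsps["query_id"].iloc[0]),
        subject_id=str(hsps["subject_id"].iloc[0]),
        cip=cip,
        calp=calp,
        n_hsps_used=len(hsps),
    )


def score_pairs(hsps: pd.DataFrame, query_lengths: dict[str, int]) -> pd.DataFrame:
    """Merge HSPs and compute CIP/CALP for every query-subject pair."""
    rows = []
    for (q, s), grp in hsps.groupby(["query_id", "subject_id"], sort=True):
        if q not in query_lengths:
            raise ValidationError(f"no query length for {q!r}")
        hit = compute_cip_calp(merge_hsps(grp), query_lengths[q])
        rows.append(
            {
                "query_id": q, "subject_id": s,
                "cip": hit.cip, "calp": hit.calp, "n_hsps_used": hit.n_hsps_used,
            }
        )
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "cip", "calp", "n_hsps_used"])


def rank_candidates(
    hits: pd.DataFrame, min_cip: float = 60.0, min_calp: float = 70.0
) -> pd.DataFrame:
    """Best subject per query: CIP desc, then CALP desc, then subject_id asc.

    ``passed`` marks hits meeting both thresholds (the best alignment is the
    highest cumulative identity over the longest cumulative length).
    """
    for t in (min_cip, min_calp):
        if not (0 <= t <= 100):
            raise ValidationError(f"thresholds must be in [0, 100] (got {t})")
    if len(hits) == 0:
        return hits.assign(passed=pd.Series(dtype=bool))
    ordered = hits.sort_values(
        ["query_id", "cip", "calp", "subject_id"],
        ascending=[True, False, False, True],
        kind="stable",
    )
    best = ordered.groupby("query_id", sort=True).head(1).reset_index(drop=True)
    best["passed"] = (best["cip"] >= min_cip) & (best["calp"] >= min_calp)
    return best
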