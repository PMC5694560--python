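"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shape of the real inputs the pipeline consumes:
several partially overlapping marker maps with monotone distortions and
occasional inversions, multi-population QTL studies scattered around true
meta-QTL positions with realistic CI widths, an ordered gene list
interleaved with anchor markers, and BLAST-tabular HSP sets with planted
identity and coverage.  Every generator is a pure function of its
parameters and seed; one seed stream per generator is derived from a master
seed so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .maps import GeneticMap
from .qtl import QTL_COLUMNS

_STREAMS = {"maps": 0, "qtl": 1, "syntenome": 2, "hsps": 3}


def stream_rng(master_seed: int, stream: str) -> np.random.Generator:
    """Independent, documented child stream of the master seed."""
    if stream not in _STREAMS:
        raise ValidationError(f"unknown stream {stream!r}")
    children = np.random.SeedSequence(master_seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


DEFAULT_CHROMOSOMES = [(f"{g}{s}", 150.0) for g in range(1, 8) for s in "ABD"]


@dataclass
class TrueMQTL:
    chromosome: str
    position: float
    trait_class: str = "GY"
    components: tuple[str, ...] = ("TKW",)


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generators (reproducible from seed)."""

    true_map: GeneticMap | None = None
    map_transforms: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    inversions: list[dict] = field(default_factory=list)
    true_mqtls: list[TrueMQTL] = field(default_factory=list)
    detected: pd.DataFrame | None = None  # qtl_id -> true MQTL bookkeeping
    planted_hits: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------


def simulate_maps(
    n_maps: int = 4,
    chromosomes: list[tuple[str, float]] | None = None,
    markers_per_chrom: int = 30,
    share_frac: float = 0.8,
    distortion_sd: float = 0.5,
    n_inversions: int = 0,
    seed: int = 0,
) -> tuple[GeneticMap, list[GeneticMap], SimulationTruth]:
    """True map plus ``n_maps`` derived maps sampled from it.

    The true map places ``markers_per_chrom`` markers uniformly per
    chromosome.  Each derived map samples ``share_frac`` of the markers,
    applies a per-chromosome monotone affine transform (the first derived
    map keeps the identity transform, mirroring the backbone convention)
    plus order-preserving jitter of sd ``distortion_sd``, and reverses
    ``n_inversions`` random marker runs (logged in the truth).  Derived
    maps overlap pairwise through the shared true marker set.
    """
    if markers_per_chrom < 2:
        raise ValidationError("markers_per_chrom must be >= 2")
    if not (0 < share_frac <= 1):
        raise ValidationError("share_frac must be in (0, 1]")
    if distortion_sd < 0:
        raise ValidationError("distortion_sd must be >= 0")
    chromosomes = chromosomes or DEFAULT_CHROMOSOMES[:3]
    rng = np.random.default_rng(seed)
    types = np.array(["SNP", "SNP", "SNP", "SSR", "DarT"])
    rows = []
    for chrom, length in chromosomes:
        pos = np.sort(rng.uniform(0, length, markers_per_chrom))
        for i, p in enumerate(pos):
            rows.append(
                {
                    "chromosome": chrom,
                    "marker": f"M_{chrom}_{i:04d}",
                    "position_cM": float(p),
                    "marker_type": str(types[i % len(types)]),
                }
            )
    true_map = GeneticMap("true", pd.DataFrame(rows))
    truth = SimulationTruth(true_map=true_map)
    derived: list[GeneticMap] = []
    for j in range(n_maps):
        map_id = f"sim_map{j}"
        truth.map_transforms[map_id] = {}
        sub_rows = []
        for chrom, length in chromosomes:
            sub = true_map.chromosome(chrom)
            n_keep = max(2, int(round(share_frac * len(sub))))
            keep = np.sort(rng.choice(len(sub), size=n_keep, replace=False))
            a, b = (0.0, 1.0) if j == 0 else (0.0, float(rng.uniform(0.85, 1.2)))
            truth.map_transforms[map_id][chrom] = (a, b)
            base = a + b * sub["position_cM"].to_numpy()[keep]
            pos = _monotone_jitter(base, distortion_sd, rng)
            for k, idx in enumerate(keep):
                r = sub.iloc[idx]
                sub_rows.append(
                    {
                        "chromosome": chrom,
                        "marker": r["marker"],
                        "position_cM": float(pos[k]),
                        "marker_type": r["marker_type"],
                    }
                )
        frame = pd.DataFrame(sub_rows)
        for _ in range(n_inversions):
            frame, logged = _invert_run(frame, map_id, rng)
            truth.inversions.append(logged)
        derived.append(GeneticMap(map_id, frame))
    return true_map, derived, truth


def _monotone_jitter(base: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive jitter, redrawn per-point so the strict order survives."""
    if sd == 0:
        return base.copy()
    out = np.empty_like(base)
    prev = -np.inf
    for i, b in enumerate(base):
        upper = base[i + 1] if i + 1 < len(base) else np.inf
        v = b + rng.normal(0, sd)
        tries = 0
        while not (prev < v < upper) and tries < 50:
            v = b + rng.normal(0, sd)
            tries += 1
        if not (prev < v < upper):
            v = b  # fall back to the undistorted position
            if v <= prev:
                v = prev + 1e-6
        out[i] = max(v, 0.0)
        if out[i] <= prev:
            out[i] = prev + 1e-6
        prev = out[i]
    return out


def _invert_run(frame: pd.DataFrame, map_id: str, rng: np.random.Generator):
    """Reverse the positions of a random short marker run on a random chromosome."""
    chroms = sorted(frame["chromosome"].unique())
    chrom = chroms[int(rng.integers(len(chroms)))]
    sub = frame[frame["chromosome"] == chrom].sort_values("position_cM")
    run_len = int(rng.integers(2, min(5, len(sub)) + 1))
    start = int(rng.integers(0, len(sub) - run_len + 1))
    idx = sub.index[start : start + run_len]
    frame = frame.copy()
    frame.loc[idx, "position_cM"] = frame.loc[idx, "position_cM"].to_numpy()[::-1]
    return frame, {
        "map": map_id,
        "chromosome": chrom,
        "markers": sub.loc[idx, "marker"].tolist(),
    }


# ---------------------------------------------------------------------------
# QTL studies
# ---------------------------------------------------------------------------


def simulate_qtl_studies(
    true_mqtls: list[TrueMQTL],
    n_populations: int = 4,
    qtls_per_mqtl: int = 1,
    scatter_sd: float | str = 2.0,
    ci_width_range: tuple[float, float] = (10.0, 25.0),
    detection_prob: float = 1.0,
    chrom_lengths: dict[str, float] | None = None,
    seed: int = 0,
    study_transforms: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Per-population QTL tables scattered around true MQTL positions.

    Each population detects each true MQTL with ``detection_prob`` and then
    reports ``qtls_per_mqtl`` QTLs whose peaks are Normal around the true
    position.  ``scatter_sd`` is either a fixed sd in cM or the string
    ``"ci"``, in which case each peak is scattered with the sd implied by
    its own CI width (width / 3.92) — the model-consistent mode.  CI width
    ~ Uniform(ci_width_range), centred on the peak and clipped to the
    chromosome; LOD ~ U(3, 15) and R2 ~ U(0.03, 0.25) as plausible dressing.

    ``study_transforms`` (population_id -> chromosome -> (a, b)) optionally
    re-expresses each population's peaks/CIs in its own study-map
    coordinates via the affine transform, matching ``simulate_maps`` truth.
    """
    if isinstance(scatter_sd, str) and scatter_sd != "ci":
        raise ValidationError("scatter_sd must be a float or 'ci'")
    if not isinstance(scatter_sd, str) and scatter_sd < 0:
        raise ValidationError("scatter_sd must be >= 0")
    if min(ci_width_range) <= 0:
        raise ValidationError("ci widths must be > 0")
    rng = np.random.default_rng(seed)
    chrom_lengths = chrom_lengths or {}
    rows = []
    book = []
    for p in range(n_populations):
        pop = f"simpop{p:02d}"
        for t, mq in enumerate(true_mqtls):
            length = chrom_lengths.get(mq.chromosome, np.inf)
            for k in range(qtls_per_mqtl):
                if rng.uniform() >= detection_prob:
                    continue
                width = float(rng.uniform(*ci_width_range))
                sd = width / 3.92 if scatter_sd == "ci" else float(scatter_sd)
                peak = float(np.clip(rng.normal(mq.position, sd) if sd > 0 else mq.position,
                                     0.0, length))
                left = max(0.0, peak - width / 2)
                right = min(float(length), peak + width / 2)
                comp = mq.components[k % len(mq.components)]
                qtl_id = f"{pop}_{mq.chromosome}_{mq.trait_class}_t{t}_q{k}"
                rows.append(
                    {
                        "qtl_id": qtl_id,
                        "population_id": pop,
                        "trait_class": mq.trait_class,
                        "trait_component": comp,
                        "chromosome": mq.chromosome,
                        "peak_cM": peak,
                        "ci_left_cM": left,
                        "ci_right_cM": right,
                        "lod": round(float(rng.uniform(3, 15)), 2),
                        "r2": round(float(rng.uniform(0.03, 0.25)), 3),
                    }
                )
                book.append({"qtl_id": qtl_id, "true_index": t, "true_position": mq.position})
    table = pd.DataFrame(rows, columns=QTL_COLUMNS)
    if study_transforms:
        for i, r in table.iterrows():
            ab = study_transforms.get(r["population_id"], {}).get(r["chromosome"])
            if ab is not None:
                a, b = ab
                for col in ("peak_cM", "ci_left_cM", "ci_right_cM"):
                    table.at[i, col] = a + b * table.at[i, col]
    truth = SimulationTruth(
        true_mqtls=list(true_mqtls),
        detected=pd.DataFrame(book, columns=["qtl_id", "true_index", "true_position"]),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Syntenome
# ---------------------------------------------------------------------------


def simulate_syntenome(
    true_map: GeneticMap,
    genes_per_interval: int = 2,
    anchor_every: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ordered gene list interleaved with backbone anchor markers.

    Genes and markers share one ordinal axis per chromosome (sequential
    slots along the chromosome), so a gene's anchored position interpolates
    strictly between its flanking markers.  Every ``anchor_every``-th marker
    is emitted as a backbone anchor with its cM.  Each gene carries a
    synthetic ortholog label.  Returns (syntenome frame, backbone frame).
    """
    rng = np.random.default_rng(seed)
    gene_rows, marker_rows = [], []
    for chrom in true_map.chromosomes:
        sub = true_map.chromosome(chrom)
        pos = sub["position_cM"].to_numpy()
        names = sub["marker"].tolist()
        ordinal = 0
        gcount = 0
        for i, (m, p) in enumerate(zip(names, pos)):
            if i % anchor_every == 0:
                marker_rows.append(
                    {"chromosome": chrom, "ordinal": ordinal, "marker": m, "consensus_cM": p}
                )
            ordinal += 1
            if i + 1 < len(names):
                for _ in range(genes_per_interval):
                    gcount += 1
                    gene_rows.append(
                        {
                            "chromosome": chrom,
                            "ordinal": ordinal,
                            "gene_id": f"G_{chrom}_{gcount:05d}",
                            "orthologs": f"Os_{chrom}_{gcount:05d};Bd_{chrom}_{gcount:05d}",
                            "scaffold": f"scaf_{chrom}_{int(rng.integers(1, 10_000)):05d}",
                        }
                    )
                    ordinal += 1
    genes = pd.DataFrame(gene_rows, columns=SYNTENOME_COLUMNS_ORDERED)
    backbone = pd.DataFrame(marker_rows, columns=["chromosome", "ordinal", "marker", "consensus_cM"])
    return genes, backbone


SYNTENOME_COLUMNS_ORDERED = ["chromosome", "ordinal", "gene_id", "orthologs", "scaffold"]


# ---------------------------------------------------------------------------
# HSPs
# ---------------------------------------------------------------------------


def simulate_hsps(
    queries: list[str],
    planted_identity: float = 90.0,
    planted_coverage: float = 80.0,
    decoys_per_query: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int], SimulationTruth]:
    """HSP table with one planted subject per query plus lower-scoring decoys.

    The planted subject's merged CIP equals ``planted_identity`` exactly and
    its CALP equals ``planted_coverage`` to within 0.5 (integer column
    rounding); decoys have strictly lower identity.  Returns
    (hsp frame, query lengths, truth with the planted subject per query).
    """
    for v in (planted_identity, planted_coverage):
        if not (0 < v <= 100):
            raise ValidationError("identity and coverage must be in (0, 100]")
    rng = np.random.default_rng(seed)
    rows = []
    lengths: dict[str, int] = {}
    truth = SimulationTruth()
    for q in queries:
        L = int(rng.integers(500, 1500))
        lengths[q] = L
        total = max(int(round(L * planted_coverage / 100.0)), 2)
        if total + 10 <= L:
            part = total // 2
            segs = [(1, part), (part + 11, part + 10 + (total - part))]  # 10-bp unaligned gap
        else:  # near-full coverage leaves no room for a gap
            segs = [(1, total)]
        subject = f"{q}_syntenic"
        for qs, qe in segs:
            alen = qe - qs + 1
            rows.append(_hsp_row(q, subject, planted_identity, alen, qs, qe, bitscore=2.0 * alen))
        truth.planted_hits[q] = {
            "subject": subject,
            "cip": planted_identity,
            "calp": min(100.0 * total / L, 100.0),
        }
        for d in range(decoys_per_query):
            ident = max(planted_identity - float(rng.uniform(8, 20)), 5.0)
            alen = max(int(round(L * float(rng.uniform(0.2, 0.6)))), 1)
            qs = int(rng.integers(1, max(L - alen, 2)))
            rows.append(
                _hsp_row(q, f"{q}_decoy{d}", ident, alen, qs, qs + alen - 1, bitscore=1.0 * alen)
            )
    frame = pd.DataFrame(rows, columns=HSP_COLUMNS_ORDERED)
    return frame, lengths, truth


def _hsp_row(q, s, ident, alen, qs, qe, bitscore):
    mism = int(round(alen * (100 - ident) / 100.0))
    return {
        "query_id": q, "subject_id": s, "percent_identity": ident,
        "alignment_length": alen, "mismatches": mism, "gap_opens": 0,
        "query_start": qs, "query_end": qe, "subject_start": qs, "subject_end": qe,
        "evalue": 1e-30, "bitscore": bitscore,
    }


HSP_COLUMNS_ORDERED = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "query_start", "query_end",
    "subject_start", "subject_end", "evalue", "bitscore",
]
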