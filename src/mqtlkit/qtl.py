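"""QTL tables and their projection onto a consensus map.

Each QTL carries a peak position, a confidence interval (CI), a trait class
(GY = grain yield, GPC = grain protein content, BQ = baking quality) and a
free-text trait component (e.g. TKW, GrN, Visco).  Projection re-expresses
peak and CI borders in consensus-map coordinates through the homothetic
anchor frame built from the markers the study map shares with the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ProjectionError, ValidationError
from .maps import AnchorFrame, GeneticMap, check_order_consistency, project_position

TRAIT_CLASSES = ("GY", "GPC", "BQ")

QTL_COLUMNS = [
    "qtl_id", "population_id", "trait_class", "trait_component",
    "chromosome", "peak_cM", "ci_left_cM", "ci_right_cM", "lod", "r2",
]

DESIGNS = ("DH", "RILs", "F2", "BC2F3", "BC2F1", "NILs", "other")


@dataclass(frozen=True)
class QTLRecord:
    qtl_id: str
    population_id: str
    trait_class: str
    trait_component: str
    chromosome: str
    peak: float
    ci_left: float | None = None
    ci_right: float | None = None
    lod: float | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.trait_class not in TRAIT_CLASSES:
            raise ValidationError(
                f"QTL {self.qtl_id!r}: unknown trait_class {self.trait_class!r} "
                f"(expected one of {TRAIT_CLASSES})"
            )
        if (self.ci_left is None) != (self.ci_right is None):
            raise ValidationError(f"QTL {self.qtl_id!r}: CI must have both borders or neither")
        if self.ci_left is not None:
            if not (self.ci_left <= self.peak <= self.ci_right):
                raise ValidationError(
                    f"QTL {self.qtl_id!r}: peak {self.peak} outside CI "
                    f"[{self.ci_left}, {self.ci_right}]"
                )
        if self.lod is not None and self.lod < 0:
            raise ValidationError(f"QTL {self.qtl_id!r}: negative LOD")
        if self.r2 is not None and not (0 <= self.r2 <= 1):
            raise ValidationError(f"QTL {self.qtl_id!r}: r2 outside [0, 1]")

    @property
    def has_ci(self) -> bool:
        return self.ci_left is not None


@dataclass(frozen=True)
class Population:
    population_id: str
    parent1: str = ""
    parent2: str = ""
    size: int = 1
    design: str = "other"

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValidationError(f"population {self.population_id!r}: size must be > 0")


@dataclass(frozen=True)
class ProjectedQTL:
    """A QTL re-expressed in consensus-map coordinates."""

    record: QTLRecord
    source_map: str
    flags: frozenset[str] = frozenset()  # extrapolated_left/right, sparse_anchors, imputed_ci

    def __getattr__(self, name):
        return getattr(self.record, name)


def read_qtl_table(path) -> list[QTLRecord]:
    """Read a tab-separated QTL table (one record per row).

    Required header columns: qtl_id, population_id, trait_class,
    trait_component, chromosome, peak_cM, ci_left_cM, ci_right_cM, lod, r2.
    Empty lod/r2/CI cells are allowed (missing CIs may later be imputed).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in QTL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return records_from_frame(frame)


def records_from_frame(frame: pd.DataFrame) -> list[QTLRecord]:
    def opt(v):
        return None if pd.isna(v) or v == "" else float(v)

    records = []
    for _, r in frame.iterrows():
        records.append(
            QTLRecord(
                qtl_id=str(r["qtl_id"]),
                population_id=str(r["population_id"]),
                trait_class=str(r["trait_class"]),
                trait_component=str(r["trait_component"]),
                chromosome=str(r["chromosome"]),
                peak=float(r["peak_cM"]),
                ci_left=opt(r["ci_left_cM"]),
                ci_right=opt(r["ci_right_cM"]),
                lod=opt(r["lod"]),
                r2=opt(r["r2"]),
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for q in records:
        rec = q.record if isinstance(q, ProjectedQTL) else q
        row = {
            "qtl_id": rec.qtl_id, "population_id": rec.population_id,
            "trait_class": rec.trait_class, "trait_component": rec.trait_component,
            "chromosome": rec.chromosome, "peak_cM": rec.peak,
            "ci_left_cM": rec.ci_left, "ci_right_cM": rec.ci_right,
            "lod": rec.lod, "r2": rec.r2,
        }
        if isinstance(q, ProjectedQTL):
            row["source_map"] = q.source_map
            row["flags"] = ";".join(sorted(q.flags))
        rows.append(row)
    cols = QTL_COLUMNS + (["source_map", "flags"] if rows and "flags" in rows[0] else [])
    return pd.DataFrame(rows, columns=cols)


def impute_ci(record: QTLRecord, width: float = 20.0) -> tuple[QTLRecord, bool]:
    """Fill a missing CI with a ``width``-cM interval centred on the peak.

    Returns (record, imputed?).  The left border is floored at 0 (the right
    border is widened symmetrically so the width is preserved).
    """
    if record.has_ci:
        return record, False
    left = record.peak - width / 2
    right = record.peak + width / 2
    if left < 0:
        right -= left
        left = 0.0
    return replace(record, ci_left=left, ci_right=right), True


def project_qtl(qtl: QTLRecord, frame: AnchorFrame, source_map: str = "") -> ProjectedQTL:
    """Project peak and CI borders through an anchor frame.

    Monotonicity of the homothetic projection preserves
    ``ci_left <= peak <= ci_right``.  Flags record extrapolation beyond the
    terminal anchors and frames with fewer than 4 anchors (``sparse_anchors``).
    """
    if frame.n_anchors < 2:
        raise ProjectionError(
            f"QTL {qtl.qtl_id!r}: fewer than 2 anchors on chromosome {qtl.chromosome!r}"
        )
    if not qtl.has_ci:
        raise ValidationError(f"QTL {qtl.qtl_id!r}: no CI; impute before projection")
    flags = set()
    if qtl.ci_left < frame.src[0]:
        flags.add("extrapolated_left")
    if qtl.ci_right > frame.src[-1]:
        flags.add("extrapolated_right")
    if frame.n_anchors < 4:
        flags.add("sparse_anchors")
    peak = project_position(qtl.peak, frame)
    left = project_position(qtl.ci_left, frame)
    right = project_position(qtl.ci_right, frame)
    rec = replace(
        qtl,
        peak=max(peak, 0.0),
        ci_left=max(left, 0.0),
        ci_right=max(right, 0.0),
    )
    return ProjectedQTL(rec, source_map=source_map, flags=frozenset(flags))


@dataclass
class ProjectionResult:
    projected: list[ProjectedQTL]
    excluded: pd.DataFrame  # qtl_id, chromosome, reason

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.projected)


def project_qtl_table(
    records: list[QTLRecord],
    source_map: GeneticMap,
    consensus: GeneticMap,
    ci_impute_width: float = 20.0,
) -> ProjectionResult:
    """Project every QTL of one study onto the consensus map.

    Anchor frames are built per chromosome from the order-consistent markers
    the study map shares with the consensus.  QTLs on chromosomes with fewer
    than two anchors, or on chromosomes absent from the consensus, are
    excluded with a logged reason (never force-placed).
    """
    report = check_order_consistency(source_map, consensus)
    frames: dict[str, AnchorFrame] = {}
    for chrom, anchors in report.retained.items():
        if len(anchors) >= 2:
            frames[chrom] = AnchorFrame.from_maps(source_map, consensus, chrom, anchors)
    projected: list[ProjectedQTL] = []
    excluded: list[dict] = []
    for rec in records:
        rec, imputed = impute_ci(rec, ci_impute_width)
        frame = frames.get(rec.chromosome)
        if frame is None:
            excluded.append(
                {
                    "qtl_id": rec.qtl_id,
                    "chromosome": rec.chromosome,
                    "reason": "no projectable anchor frame on chromosome",
                }
            )
            continue
        p = project_qtl(rec, frame, source_map=source_map.map_id)
        if imputed:
            p = ProjectedQTL(p.record, p.source_map, p.flags | {"imputed_ci"})
        projected.append(p)
    return ProjectionResult(
        projected, pd.DataFrame(excluded, columns=["qtl_id", "chromosome", "reason"])
    )
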