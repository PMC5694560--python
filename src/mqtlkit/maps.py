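"""Genetic maps: reading, order-consistency checking, homothetic merging.

A genetic map is an ordered set of markers per chromosome with positions in
centiMorgans (cM).  Several partially overlapping maps are combined into a
single consensus map by *homothetic projection*: positions of markers unique
to an incoming map are rescaled piecewise-linearly between the markers it
shares with the consensus (the *anchors*).  Before merging, markers whose
order disagrees between two maps (typically genotype-specific inversions or
mapping errors) are detected and discarded from the incoming map.
"""

from __future__ import annotations

import io
import re
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MapFormatError, ProjectionError, ValidationError

MARKER_TYPES = ("SNP", "SSR", "RFLP", "DarT", "Gene")

MAP_COLUMNS = ["chromosome", "marker", "position_cM", "marker_type"]

_WHEAT_CHROM = re.compile(r"([1-7])([ABD])")


@dataclass(frozen=True)
class Marker:
    """A single mapped locus."""

    name: str
    chromosome: str
    position: float
    marker_type: str = "SNP"
    source_map: str = ""

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"marker {self.name!r}: negative position {self.position}")
        if not self.chromosome:
            raise ValidationError(f"marker {self.name!r}: empty chromosome label")


class GeneticMap:
    """Ordered markers with cM positions per chromosome.

    Internally a pandas DataFrame with columns ``chromosome``, ``marker``,
    ``position_cM``, ``marker_type``, ``source_map``, kept sorted by
    (chromosome, position, marker) — ties broken by name for reproducibility.
    A marker name appears at most once within a map.
    """

    COLUMNS = MAP_COLUMNS + ["source_map"]

    def __init__(self, map_id: str, frame: pd.DataFrame):
        frame = frame.copy()
        if "source_map" not in frame.columns:
            frame["source_map"] = map_id
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise MapFormatError(f"map {map_id!r}: missing columns {missing}")
        frame = frame[self.COLUMNS]
        frame["position_cM"] = frame["position_cM"].astype(float)
        if (frame["position_cM"] < 0).any():
            bad = frame.loc[frame["position_cM"] < 0, "marker"].tolist()
            raise ValidationError(f"map {map_id!r}: negative positions for {bad[:5]}")
        dup = frame["marker"][frame["marker"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"map {map_id!r}: duplicate marker names {sorted(set(dup))[:5]}"
            )
        frame = frame.sort_values(
            ["chromosome", "position_cM", "marker"], kind="stable"
        ).reset_index(drop=True)
        self.map_id = map_id
        self.frame = frame

    # -- container conveniences -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return f"GeneticMap({self.map_id!r}, {len(self)} markers, {len(self.chromosomes)} chromosomes)"

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.frame["chromosome"].unique())

    def chromosome(self, label: str) -> pd.DataFrame:
        """Markers of one chromosome, position-sorted."""
        return self.frame[self.frame["chromosome"] == label]

    def positions(self, label: str) -> pd.Series:
        """Mapping marker name -> cM position for one chromosome."""
        sub = self.chromosome(label)
        return pd.Series(sub["position_cM"].values, index=sub["marker"].values)

    @classmethod
    def from_markers(cls, map_id: str, markers: list[Marker]) -> "GeneticMap":
        frame = pd.DataFrame(
            {
                "chromosome": [m.chromosome for m in markers],
                "marker": [m.name for m in markers],
                "position_cM": [m.position for m in markers],
                "marker_type": [m.marker_type for m in markers],
                "source_map": [m.source_map or map_id for m in markers],
            }
        )
        return cls(map_id, frame)

    def copy(self, map_id: str | None = None) -> "GeneticMap":
        return GeneticMap(map_id or self.map_id, self.frame)

    def equals(self, other: "GeneticMap") -> bool:
        a = self.frame[MAP_COLUMNS].reset_index(drop=True)
        b = other.frame[MAP_COLUMNS].reset_index(drop=True)
        return a.equals(b)

    def to_tsv(self, path) -> None:
        """Write the map in the interchange format (positions at 2 decimals)."""
        out = self.frame[MAP_COLUMNS].copy()
        out["position_cM"] = out["position_cM"].map(lambda v: f"{v:.2f}")
        out.to_csv(path, sep="\t", index=False)


def read_map(path, map_id: str) -> GeneticMap:
    """Read a tab-separated genetic map table.

    Expected header: ``chromosome  marker  position_cM  marker_type``.
    Rows with non-numeric or negative positions raise :class:`ValidationError`
    naming the offending line (header = line 1).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MAP_COLUMNS if c not in frame.columns]
    if missing:
        raise MapFormatError(f"{path}: missing required columns {missing}")
    pos = pd.to_numeric(frame["position_cM"], errors="coerce")
    bad = frame.index[pos.isna() | (pos < 0)]
    if len(bad):
        i = int(bad[0])
        raise ValidationError(
            f"{path}: line {i + 2}: invalid position_cM {frame.loc[i, 'position_cM']!r} "
            f"for marker {frame.loc[i, 'marker']!r}"
        )
    dup = frame["marker"][frame["marker"].duplicated()]
    if len(dup):
        i = int(dup.index[0])
        raise ValidationError(f"{path}: line {i + 2}: duplicate marker {frame.loc[i, 'marker']!r}")
    frame = frame.assign(position_cM=pos)
    return GeneticMap(map_id, frame)


# ---------------------------------------------------------------------------
# Order consistency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Conflict:
    marker: str
    map_a: str
    map_b: str
    chromosome_a: str
    chromosome_b: str
    reason: str  # "order" | "chromosome_assignment"


@dataclass
class ConsistencyReport:
    """Outcome of a pairwise marker-order check.

    ``retained`` maps chromosome label (in map_a) to the maximum-cardinality
    list of shared markers whose order agrees in both maps; every other shared
    marker appears in ``conflicts``.
    """

    map_a: str
    map_b: str
    conflicts: list[Conflict] = field(default_factory=list)
    retained: dict[str, list[str]] = field(default_factory=dict)

    def conflicted_names(self) -> set[str]:
        return {c.marker for c in self.conflicts}

    def n_retained(self) -> int:
        return sum(len(v) for v in self.retained.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "marker": c.marker,
                "map_a": c.map_a,
                "map_b": c.map_b,
                "chromosome_a": c.chromosome_a,
                "chromosome_b": c.chromosome_b,
                "reason": c.reason,
            }
            for c in self.conflicts
        ]
        return pd.DataFrame(
            rows,
            columns=["marker", "map_a", "map_b", "chromosome_a", "chromosome_b", "reason"],
        )


def _max_nondecreasing_subsequence(values: np.ndarray) -> list[int]:
    """Indices of one longest non-decreasing subsequence (patience sorting)."""
    tails: list[float] = []  # smallest tail value of a subsequence of length i+1
    tail_idx: list[int] = []
    parent = [-1] * len(values)
    for i, v in enumerate(values):
        j = bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            tail_idx.append(i)
        else:
            tails[j] = v
            tail_idx[j] = i
        parent[i] = tail_idx[j - 1] if j > 0 else -1
    out: list[int] = []
    i = tail_idx[-1] if tail_idx else -1
    while i >= 0:
        out.append(i)
        i = parent[i]
    return out[::-1]


def check_order_consistency(map_a: GeneticMap, map_b: GeneticMap) -> ConsistencyReport:
    """Flag shared markers whose order or chromosome differs between two maps.

    Per chromosome, the retained set is a maximum-cardinality subset of shared
    markers whose relative order (ties permitted) is identical in both maps —
    a longest common monotone subsequence of the shared-marker ranks.  Shared
    markers assigned to different chromosomes are flagged with reason
    ``chromosome_assignment`` regardless of positions.
    """
    report = ConsistencyReport(map_a.map_id, map_b.map_id)
    a = map_a.frame.set_index("marker")
    b = map_b.frame.set_index("marker")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        return report
    chrom_a = a.loc[shared, "chromosome"]
    chrom_b = b.loc[shared, "chromosome"]
    mismatched = shared[(chrom_a != chrom_b).values]
    for name in mismatched:
        report.conflicts.append(
            Conflict(
                name, map_a.map_id, map_b.map_id,
                a.at[name, "chromosome"], b.at[name, "chromosome"],
                "chromosome_assignment",
            )
        )
    same = shared.difference(mismatched)
    for chrom in sorted(a.loc[same, "chromosome"].unique()):
        names = [n for n in same if a.at[n, "chromosome"] == chrom]
        # order by map_a; tie-break by map_b position so that ties in map_a
        # can never force a spurious order conflict
        names.sort(key=lambda n: (a.at[n, "position_cM"], b.at[n, "position_cM"], n))
        pos_b = np.array([b.at[n, "position_cM"] for n in names], dtype=float)
        keep = set(_max_nondecreasing_subsequence(pos_b))
        report.retained[chrom] = [n for i, n in enumerate(names) if i in keep]
        for i, n in enumerate(names):
            if i not in keep:
                report.conflicts.append(
                    Conflict(n, map_a.map_id, map_b.map_id, chrom, chrom, "order")
                )
    return report


# ---------------------------------------------------------------------------
# Homothetic projection
# ---------------------------------------------------------------------------


class AnchorFrame:
    """Ordered (source cM, destination cM) anchor pairs for one chromosome.

    Anchors sharing a source position are collapsed to a single anchor at the
    mean of their destinations, so source positions are strictly increasing.
    Destination positions must be non-decreasing (anchors are built from
    order-consistent shared markers), which makes the projection monotone.
    """

    def __init__(self, pairs, chromosome: str | None = None):
        pairs = sorted((float(s), float(d)) for s, d in pairs)
        src: list[float] = []
        dst: list[float] = []
        i = 0
        while i < len(pairs):
            j = i
            while j < len(pairs) and pairs[j][0] == pairs[i][0]:
                j += 1
            src.append(pairs[i][0])
            dst.append(float(np.mean([p[1] for p in pairs[i:j]])))
            i = j
        self.src = np.array(src)
        self.dst = np.array(dst)
        self.chromosome = chromosome
        if np.any(np.diff(self.dst) < 0):
            raise ProjectionError(
                f"anchor destinations not monotone on {chromosome!r}; "
                "filter order-inconsistent markers first"
            )

    @property
    def n_anchors(self) -> int:
        return len(self.src)

    def inverse(self) -> "AnchorFrame":
        if np.any(np.diff(self.dst) <= 0):
            raise ProjectionError("frame not invertible (non-increasing destinations)")
        return AnchorFrame(zip(self.dst, self.src), self.chromosome)

    @classmethod
    def from_maps(
        cls, source: GeneticMap, dest: GeneticMap, chromosome: str, markers: list[str]
    ) -> "AnchorFrame":
        """Frame keyed by shared ``markers`` present on ``chromosome`` in both maps."""
        ps = source.positions(chromosome)
        pd_ = dest.positions(chromosome)
        pairs = [(ps[m], pd_[m]) for m in markers if m in ps.index and m in pd_.index]
        return cls(pairs, chromosome)

    def project(self, p):
        return project_position(p, self)


def project_position(p, frame: AnchorFrame):
    """Piecewise-linear (homothetic) projection of cM position(s) ``p``.

    Between consecutive anchors (a_s, a_d), (b_s, b_d):
    ``p' = a_d + (p - a_s) * (b_d - a_d) / (b_s - a_s)``.  Outside the anchored
    range, the terminal interval's scale factor is extended; a terminal
    interval with zero destination length extrapolates at scale 1.
    """
    if frame.n_anchors < 2:
        raise ProjectionError(
            f"need >=2 anchors to project (got {frame.n_anchors})"
        )
    x = np.asarray(p, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.interp(x, frame.src, frame.dst)
    lo = x < frame.src[0]
    if lo.any():
        slope = (frame.dst[1] - frame.dst[0]) / (frame.src[1] - frame.src[0])
        if slope == 0:
            slope = 1.0
        out[lo] = frame.dst[0] + (x[lo] - frame.src[0]) * slope
    hi = x > frame.src[-1]
    if hi.any():
        slope = (frame.dst[-1] - frame.dst[-2]) / (frame.src[-1] - frame.src[-2])
        if slope == 0:
            slope = 1.0
        out[hi] = frame.dst[-1] + (x[hi] - frame.src[-1]) * slope
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


@dataclass
class MergeResult:
    consensus: GeneticMap
    conflicts: list[Conflict]
    unplaced: pd.DataFrame  # marker, map, chromosome, reason

    def conflicts_frame(self) -> pd.DataFrame:
        return ConsistencyReport("", "", conflicts=self.conflicts).to_frame()


def merge_maps(
    maps: list[GeneticMap], order: str = "given", consensus_id: str = "consensus"
) -> MergeResult:
    """Merge maps into a consensus by iterative homothetic projection.

    The first map is the backbone.  Each subsequent map is checked against the
    running consensus; markers flagged order- or chromosome-inconsistent are
    dropped from the incoming map only.  Unique markers are projected through
    the per-chromosome anchor frame of retained shared markers; shared markers
    keep their consensus position.  Chromosomes with fewer than two usable
    anchors contribute no projected markers (recorded in ``unplaced``).

    order="by-size" merges in descending marker count (densest backbone).
    """
    if not maps:
        raise ValidationError("merge_maps: empty map list")
    if order == "by-size":
        maps = sorted(maps, key=lambda m: -len(m))
    elif order != "given":
        raise ValidationError(f"merge_maps: unknown order {order!r}")
    consensus = maps[0].copy(consensus_id)
    all_conflicts: list[Conflict] = []
    unplaced_rows: list[dict] = []
    for incoming in maps[1:]:
        report = check_order_consistency(consensus, incoming)
        all_conflicts.extend(report.conflicts)
        dropped = report.conflicted_names()
        retained_by_chrom = report.retained
        inc = incoming.frame[~incoming.frame["marker"].isin(dropped)]
        shared_all = set(consensus.frame["marker"])
        new_rows = [consensus.frame]
        for chrom in sorted(inc["chromosome"].unique()):
            sub = inc[inc["chromosome"] == chrom]
            unique = sub[~sub["marker"].isin(shared_all)]
            if len(unique) == 0:
                continue
            anchors = retained_by_chrom.get(chrom, [])
            if len(anchors) < 2:
                for _, r in unique.iterrows():
                    unplaced_rows.append(
                        {
                            "marker": r["marker"],
                            "map": incoming.map_id,
                            "chromosome": chrom,
                            "reason": "fewer than 2 shared anchors",
                        }
                    )
                continue
            frame = AnchorFrame.from_maps(incoming, consensus, chrom, anchors)
            proj = unique.copy()
            proj["position_cM"] = np.maximum(
                project_position(unique["position_cM"].to_numpy(), frame), 0.0
            )
            new_rows.append(proj)
        merged = pd.concat(new_rows, ignore_index=True)
        consensus = GeneticMap(consensus_id, merged)
    unplaced = pd.DataFrame(unplaced_rows, columns=["marker", "map", "chromosome", "reason"])
    return MergeResult(consensus, all_conflicts, unplaced)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

_GROUPINGS = {
    "chromosome_by_type": "chromosome_by_type",
    "chromosome": "chromosome_by_type",
    "homoeologous_group": "homoeologous_group",
    "group": "homoeologous_group",
    "subgenome": "subgenome",
    "grand_total": "grand_total",
    "total": "grand_total",
}


def _wheat_parse(labels: pd.Series, what: str) -> pd.Series:
    m = labels.str.fullmatch(_WHEAT_CHROM.pattern)
    if not m.all():
        bad = sorted(labels[~m].unique())
        raise ValidationError(
            f"wheat grouping needs chromosome labels 1A..7D; offending labels {bad[:5]}"
        )
    return labels.str[0] if what == "group" else labels.str[1]


def summarize_map(gmap: GeneticMap, grouping: str) -> pd.DataFrame:
    """Marker-count summary of a map.

    grouping: ``chromosome_by_type`` (chromosome x marker-type counts with a
    Total row/column), ``homoeologous_group`` (wheat groups 1-7),
    ``subgenome`` (wheat A/B/D), or ``grand_total``.
    """
    key = _GROUPINGS.get(grouping)
    if key is None:
        raise ValidationError(f"unknown grouping {grouping!r}")
    frame = gmap.frame
    if key == "grand_total":
        return pd.DataFrame({"grand_total": [len(frame)]})
    if key == "chromosome_by_type":
        if len(frame) == 0:
            return pd.DataFrame({"Total": [0]}, index=pd.Index([], name="chromosome")).iloc[:0]
        tab = pd.crosstab(frame["chromosome"], frame["marker_type"])
        tab["Total"] = tab.sum(axis=1)
        tab.loc["Total"] = tab.sum(axis=0)
        return tab
    groups = ["1", "2", "3", "4", "5", "6", "7"] if key == "homoeologous_group" else ["A", "B", "D"]
    col = "homoeologous_group" if key == "homoeologous_group" else "subgenome"
    if len(frame) == 0:
        return pd.DataFrame({col: groups, "n_markers": [0] * len(groups)})
    labels = _wheat_parse(frame["chromosome"], "group" if col == "homoeologous_group" else "sub")
    counts = labels.value_counts()
    return pd.DataFrame({col: groups, "n_markers": [int(counts.get(g, 0)) for g in groups]})
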