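"""Meta-QTL analysis: weighted Gaussian clustering of projected QTLs.

Each projected QTL contributes an observation x_i (its peak, cM) with a
position standard deviation s_i derived from its 95% CI (s = width / 3.92,
the Gaussian convention).  Within a chromosome x trait-class group, the QTLs
are modelled as K true meta-QTL positions mu_1 < ... < mu_K with
x_i ~ N(mu_k(i), s_i^2) and hard, contiguous assignment of the x-sorted
observations.  The maximum-likelihood partition for each K is found exactly
by dynamic programming over breakpoints; K is chosen among {1, 2, 3, 4} and
the degenerate n-model (one cluster per QTL) by an information criterion.
If the n-model wins (more than four meta-QTLs supported), the chromosome is
split at QTL-free gaps and each segment is analysed independently.

A cluster becomes a meta-QTL (MQTL) only when it holds at least two QTLs
from at least two distinct populations; its consensus position is the
precision-weighted mean and its 95% CI is mu +/- 1.96 / sqrt(sum of weights).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .qtl import ProjectedQTL

LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)

CRITERIA = ("awe", "maic", "aic", "aicc", "bic")

#: Largest explicit cluster count fitted before falling back to the n-model.
MAX_K = 4

#: Groups larger than this are segmented before analysis (termination guard).
MAX_GROUP_SIZE = 25


def std_from_ci(ci_left: float, ci_right: float) -> float:
    """Position standard deviation implied by a 95% CI: (right - left) / 3.92."""
    width = ci_right - ci_left
    if width <= 0:
        raise ValidationError(f"CI width must be positive (got {width})")
    return width / 3.92


@dataclass(frozen=True)
class QTLObservation:
    """One projected QTL as seen by the clustering model."""

    x: float
    s: float
    qtl_id: str = ""
    population_id: str = ""
    trait_component: str = ""
    ci_left: float | None = None
    ci_right: float | None = None

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValidationError(f"observation {self.qtl_id!r}: s must be > 0")

    @property
    def weight(self) -> float:
        return 1.0 / (self.s * self.s)

    @classmethod
    def from_projected(cls, q: ProjectedQTL) -> "QTLObservation":
        return cls(
            x=q.peak,
            s=std_from_ci(q.ci_left, q.ci_right),
            qtl_id=q.qtl_id,
            population_id=q.population_id,
            trait_component=q.trait_component,
            ci_left=q.ci_left,
            ci_right=q.ci_right,
        )


@dataclass
class ClusterModel:
    """A fitted contiguous K-partition of x-sorted observations."""

    K: int
    assignment: list[list[int]]  # index blocks into the sorted observation list
    mu: np.ndarray
    cluster_var: np.ndarray  # pooled variance 1 / sum(w_i) per cluster
    logL: float
    criterion: float | None = None
    observations: list[QTLObservation] = field(default_factory=list)

    def members(self, k: int) -> list[QTLObservation]:
        return [self.observations[i] for i in self.assignment[k]]


def _sort_observations(obs: list[QTLObservation]) -> list[QTLObservation]:
    return sorted(obs, key=lambda o: (o.x, o.qtl_id))


def _prefix_sums(x: np.ndarray, w: np.ndarray):
    z = np.zeros(len(x) + 1)
    cw, cwx, cwx2 = z.copy(), z.copy(), z.copy()
    cw[1:] = np.cumsum(w)
    cwx[1:] = np.cumsum(w * x)
    cwx2[1:] = np.cumsum(w * x * x)
    return cw, cwx, cwx2


def _block_cost(cw, cwx, cwx2, i: int, j: int) -> float:
    """Weighted SSE of observations i..j (inclusive) around their weighted mean."""
    W = cw[j + 1] - cw[i]
    S = cwx[j + 1] - cwx[i]
    return max(cwx2[j + 1] - cwx2[i] - S * S / W, 0.0)


def fit_k_clusters(obs: list[QTLObservation], K: int) -> ClusterModel:
    """Maximum-likelihood contiguous partition into K clusters.

    Maximises  sum_i [ -((x_i - mu_k(i)) / s_i)^2 / 2 - ln(s_i sqrt(2 pi)) ]
    with mu_k the precision-weighted mean of its block, via O(n^2 K) dynamic
    programming over breakpoints.  Exact: equals exhaustive enumeration over
    all contiguous K-partitions.
    """
    n = len(obs)
    if K <= 0 or K > n:
        raise AnalysisError(f"K must be in 1..{n} (got {K})")
    obs = _sort_observations(obs)
    x = np.array([o.x for o in obs])
    s = np.array([o.s for o in obs])
    w = 1.0 / (s * s)
    cw, cwx, cwx2 = _prefix_sums(x, w)
    D = np.full((K + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    back = np.zeros((K + 1, n + 1), dtype=int)
    for k in range(1, K + 1):
        for j in range(k, n + 1):
            best, arg = np.inf, k - 1
            for i in range(k - 1, j):
                v = D[k - 1, i] + _block_cost(cw, cwx, cwx2, i, j - 1)
                if v < best:
                    best, arg = v, i
            D[k, j] = best
            back[k, j] = arg
    cuts: list[tuple[int, int]] = []
    j = n
    for k in range(K, 0, -1):
        i = int(back[k, j])
        cuts.append((i, j))
        j = i
    cuts.reverse()
    assignment = [list(range(a, b)) for a, b in cuts]
    mu = np.array([(cwx[b] - cwx[a]) / (cw[b] - cw[a]) for a, b in cuts])
    var = np.array([1.0 / (cw[b] - cw[a]) for a, b in cuts])
    logL = -float(np.sum(np.log(s))) - n * LOG_SQRT_2PI - 0.5 * float(D[K, n])
    return ClusterModel(K, assignment, mu, var, logL, observations=obs)


def _n_model(obs: list[QTLObservation]) -> ClusterModel:
    obs = _sort_observations(obs)
    n = len(obs)
    x = np.array([o.x for o in obs])
    s = np.array([o.s for o in obs])
    logL = -float(np.sum(np.log(s))) - n * LOG_SQRT_2PI
    return ClusterModel(
        n, [[i] for i in range(n)], x.copy(), s * s, logL, observations=obs
    )


def information_criterion(logL: float, K: int, n: int, criterion: str = "awe") -> float:
    """Penalised model-selection score (lower is better).

    The free parameters of the contiguous K-cluster model are counted as
    p = 2K - 1: the K cluster positions plus the K - 1 ordered breakpoints.
    Counting breakpoints matters: the breakpoint search inflates the
    likelihood, and a plain "K positions" AIC systematically overfits K.

    - ``awe``  (default): -2 logL + p (3 + 2 ln n) — the Banfield-Raftery
      approximate-weight-of-evidence criterion for classification (hard
      assignment) likelihoods, which is exactly this model's form.
    - ``maic``: small-sample-corrected Akaike with p = 2K - 1 (the
      "modified AIC" family); the correction denominator is floored at 1.
    - ``aic`` / ``aicc`` / ``bic``: classical forms with p = K positions.
    """
    if criterion not in CRITERIA:
        raise AnalysisError(f"unknown criterion {criterion!r} (choose from {CRITERIA})")
    p = 2 * K - 1
    if criterion == "awe":
        return -2 * logL + p * (3 + 2 * math.log(n))
    if criterion == "maic":
        return -2 * logL + 2 * p + 2 * p * (p + 1) / max(n - p - 1, 1)
    if criterion == "aic":
        return -2 * logL + 2 * K
    if criterion == "aicc":
        return -2 * logL + 2 * K + 2 * K * (K + 1) / max(n - K - 1, 1)
    return -2 * logL + K * math.log(n)  # bic


def candidate_models(obs: list[QTLObservation]) -> list[ClusterModel]:
    """The K in {1..4} models (bounded by n) plus the n-model, K-ascending."""
    n = len(obs)
    models = [fit_k_clusters(obs, K) for K in range(1, min(MAX_K, n) + 1)]
    if n > MAX_K:
        models.append(_n_model(obs))
    return models


def select_model(obs: list[QTLObservation], criterion: str = "awe") -> ClusterModel:
    """Fit all candidate cluster counts and return the criterion-minimal model.

    Ties are broken toward smaller K (parsimony).
    """
    if not obs:
        raise AnalysisError("select_model: no observations")
    n = len(obs)
    best: ClusterModel | None = None
    for model in candidate_models(obs):
        model.criterion = information_criterion(model.logL, model.K, n, criterion)
        if best is None or model.criterion < best.criterion - 1e-9:
            best = model
    return best


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    chromosome: str
    left: float
    right: float
    observations: list[QTLObservation]


def split_segments(
    obs: list[QTLObservation], chromosome: str = ""
) -> list[Segment]:
    """Split at QTL-free gaps: connected components of the union of member CIs.

    Touching intervals (shared endpoint) belong to one segment; only open
    gaps of positive length separate segments.  Observations without a CI
    use x +/- 1.96 s.
    """
    if not obs:
        return []
    def ival(o: QTLObservation) -> tuple[float, float]:
        if o.ci_left is not None and o.ci_right is not None:
            return (o.ci_left, o.ci_right)
        return (o.x - 1.96 * o.s, o.x + 1.96 * o.s)

    items = sorted(obs, key=lambda o: (ival(o)[0], o.x, o.qtl_id))
    segments: list[Segment] = []
    cur: list[QTLObservation] = []
    left = right = None
    for o in items:
        lo, hi = ival(o)
        if left is None or lo > right:  # strict: touching intervals merge
            if cur:
                segments.append(Segment(chromosome, left, right, cur))
            cur, left, right = [o], lo, hi
        else:
            cur.append(o)
            right = max(right, hi)
    segments.append(Segment(chromosome, left, right, cur))
    return segments


def consensus_interval(members: list[QTLObservation]) -> tuple[float, tuple[float, float]]:
    """Precision-pooled position and 95% CI of a cluster.

    var = 1 / sum(w_i); CI = mu +/- 1.96 sqrt(var).  Pooling: the consensus
    variance never exceeds the smallest member variance.
    """
    if not members:
        raise AnalysisError("consensus_interval: empty cluster")
    w = np.array([m.weight for m in members])
    x = np.array([m.x for m in members])
    mu = float(np.sum(w * x) / np.sum(w))
    half = 1.96 * math.sqrt(1.0 / float(np.sum(w)))
    return mu, (mu - half, mu + half)


# ---------------------------------------------------------------------------
# Full meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class MQTL:
    mqtl_id: str
    trait_class: str
    chromosome: str
    position: float
    ci_left: float
    ci_right: float
    member_qtls: list[str]
    n_populations: int
    components: list[str]

    @property
    def width(self) -> float:
        return self.ci_right - self.ci_left


@dataclass
class MetaResult:
    mqtls: list[MQTL]
    audit: pd.DataFrame  # one row per input QTL: status mqtl_member | unresolved

    def report_frame(self) -> pd.DataFrame:
        from .report import mqtl_report_frame

        return mqtl_report_frame(self.mqtls)


def _analyse_group(
    obs: list[QTLObservation], criterion: str, depth: int, log: list[str], chromosome: str
) -> list[ClusterModel]:
    """Select a model for one group, segmenting and recursing when needed."""
    n = len(obs)
    if n == 0:
        return []
    if depth >= 3:
        log.append(f"{chromosome}: recursion depth cap reached with {n} observations")
        return [select_model(obs, criterion)]
    if n > MAX_GROUP_SIZE:
        segments = split_segments(obs, chromosome)
        if len(segments) > 1:
            out: list[ClusterModel] = []
            for seg in segments:
                out.extend(_analyse_group(seg.observations, criterion, depth + 1, log, chromosome))
            return out
        log.append(f"{chromosome}: {n} observations but no QTL-free gap to split at")
    model = select_model(obs, criterion)
    if model.K == n and n > MAX_K:
        segments = split_segments(obs, chromosome)
        if len(segments) > 1:
            out = []
            for seg in segments:
                out.extend(_analyse_group(seg.observations, criterion, depth + 1, log, chromosome))
            return out
        log.append(f"{chromosome}: n-model selected but chromosome has no QTL-free gap")
    return [model]


def run_meta_analysis(
    projected: list[ProjectedQTL],
    criterion: str = "awe",
    min_populations: int = 2,
    mqtl_prefix: str = "MQTL",
) -> MetaResult:
    """Cluster projected QTLs into MQTLs per (trait_class, chromosome) group.

    Clusters with >= 2 member QTLs from >= ``min_populations`` distinct
    populations become MQTLs; all other clusters are reported as unresolved
    in the audit table (never silently dropped).  MQTL ids are assigned in
    (trait_class, chromosome, position) order.
    """
    groups: dict[tuple[str, str], list[ProjectedQTL]] = {}
    for q in projected:
        groups.setdefault((q.trait_class, q.chromosome), []).append(q)
    log: list[str] = []
    audit_rows: list[dict] = []
    raw: list[tuple[str, str, float, tuple[float, float], list[QTLObservation]]] = []
    for (trait, chrom) in sorted(groups):
        obs = [QTLObservation.from_projected(q) for q in groups[(trait, chrom)]]
        models = _analyse_group(obs, criterion, 0, log, chrom)
        for model in models:
            for k in range(model.K):
                members = model.members(k)
                mu, ci = consensus_interval(members)
                raw.append((trait, chrom, mu, ci, members))
    raw.sort(key=lambda t: (t[0], t[1], t[2]))
    mqtls: list[MQTL] = []
    counter = 0
    for trait, chrom, mu, ci, members in raw:
        pops = {m.population_id for m in members}
        qtl_ids = sorted(m.qtl_id for m in members)
        if len(members) >= 2 and len(pops) >= min_populations:
            counter += 1
            mid = f"{mqtl_prefix}{counter}"
            mqtls.append(
                MQTL(
                    mqtl_id=mid,
                    trait_class=trait,
                    chromosome=chrom,
                    position=mu,
                    ci_left=ci[0],
                    ci_right=ci[1],
                    member_qtls=qtl_ids,
                    n_populations=len(pops),
                    components=sorted({m.trait_component for m in members if m.trait_component}),
                )
            )
            status, target = "mqtl_member", mid
        else:
            reason = (
                "single QTL cluster" if len(members) < 2 else "members from a single population"
            )
            status, target = "unresolved", reason
        for m in members:
            audit_rows.append(
                {
                    "qtl_id": m.qtl_id,
                    "trait_class": trait,
                    "chromosome": chrom,
                    "population_id": m.population_id,
                    "status": status,
                    "detail": target,
                }
            )
    audit = pd.DataFrame(
        audit_rows,
        columns=["qtl_id", "trait_class", "chromosome", "population_id", "status", "detail"],
    )
    result = MetaResult(mqtls, audit)
    result.log = log
    return result
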