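"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own algorithms: exhaustive
enumeration over subsets (marker-order consistency) and over contiguous
partitions (weighted Gaussian clustering), so the dynamic programs can be
checked against ground truth on small instances.
"""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mqtlkit.maps import GeneticMap

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def brute_force_max_monotone(ranks_b: list[float]) -> int:
    """Max cardinality of a non-decreasing subsequence, by subset enumeration."""
    n = len(ranks_b)
    best = 0
    for size in range(n, best, -1):
        for idx in combinations(range(n), size):
            vals = [ranks_b[i] for i in idx]
            if all(vals[i] <= vals[i + 1] for i in range(len(vals) - 1)):
                return size
    return best


def exhaustive_best_loglik(x: np.ndarray, s: np.ndarray, K: int) -> float:
    """Best contiguous-K-partition log-likelihood by enumerating breakpoints."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    x, s = x[order], s[order]
    w = 1.0 / s**2
    const = -float(np.sum(np.log(s))) - n * 0.5 * math.log(2 * math.pi)
    best = -np.inf
    for cuts in combinations(range(1, n), K - 1):
        bounds = [0, *cuts, n]
        sse = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            ww, xx = w[a:b], x[a:b]
            mu = np.sum(ww * xx) / np.sum(ww)
            sse += float(np.sum(ww * (xx - mu) ** 2))
        best = max(best, const - 0.5 * sse)
    return best


def make_map(map_id: str, markers: dict[str, list[tuple[str, float]]]) -> GeneticMap:
    """Build a map from {chromosome: [(marker, position), ...]}."""
    rows = []
    for chrom, items in markers.items():
        for name, pos in items:
            rows.append(
                {"chromosome": chrom, "marker": name, "position_cM": pos, "marker_type": "SNP"}
            )
    return GeneticMap(map_id, pd.DataFrame(rows))


@pytest.fixture
def simple_map():
    return make_map("A", {"1A": [("m1", 0.0), ("m2", 10.0), ("m3", 20.0)]})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def build_noise_free_study(seed: int = 123):
    """In-memory no-noise synthetic inputs: maps, per-population studies
    and the planted MQTL truth (for exact end-to-end collapse checks)."""
    from mqtlkit.qtl import records_from_frame
    from mqtlkit.simulate import TrueMQTL, simulate_maps, simulate_qtl_studies

    true_map, derived, truth = simulate_maps(
        n_maps=3, chromosomes=[("1A", 150.0), ("2B", 150.0)], markers_per_chrom=20,
        share_frac=1.0, distortion_sd=0.0, n_inversions=0, seed=seed,
    )
    planted = [TrueMQTL("1A", 20.0, "GY", ("TKW",)), TrueMQTL("1A", 60.0, "GY", ("Th",))]
    pops = [f"simpop{p:02d}" for p in range(4)]
    transforms = {
        pops[p]: truth.map_transforms[derived[p % len(derived)].map_id] for p in range(4)
    }
    table, _ = simulate_qtl_studies(
        planted, n_populations=4, qtls_per_mqtl=1, scatter_sd=0.0,
        ci_width_range=(8.0, 8.0), detection_prob=1.0,
        chrom_lengths={"1A": 150.0}, seed=seed + 1, study_transforms=transforms,
    )
    studies = []
    for p, pop in enumerate(pops):
        sub = table[table["population_id"] == pop]
        studies.append((records_from_frame(sub), derived[p % len(derived)]))
    return derived, studies, planted
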