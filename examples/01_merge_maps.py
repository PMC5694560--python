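"""Merge three partially overlapping genetic maps into a consensus map.

Simulates a true map plus three distorted derived maps (one carrying a
marker-order inversion), removes order-inconsistent markers, and merges the
rest by homothetic projection.  The consensus keeps the backbone's
coordinate system and gains every projectable unique marker.
"""

from mqtlkit import merge_maps, summarize_map
from mqtlkit.simulate import simulate_maps

true_map, derived, truth = simulate_maps(
    n_maps=3,
    chromosomes=[("1A", 150.0), ("2B", 130.0)],
    markers_per_chrom=40,
    share_frac=0.6,       # each derived map samples 60% of the true markers
    distortion_sd=0.4,    # order-preserving positional jitter, cM
    n_inversions=1,       # one genotype-specific inversion, logged in truth
    seed=42,
)

result = merge_maps(derived, order="by-size")
print(f"input maps: {[len(m) for m in derived]} markers")
print(f"consensus : {len(result.consensus)} markers")
print(f"conflicts removed from incoming maps: {len(result.conflicts)}")
print(f"unplaced (too few anchors): {len(result.unplaced)}")
print(summarize_map(result.consensus, "chromosome_by_type"))
# The consensus marker count equals backbone + unique projectable markers of
# the other maps; conflicted markers (e.g. the planted inversion) are dropped
# from the incoming map only and listed with a machine-readable reason.
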