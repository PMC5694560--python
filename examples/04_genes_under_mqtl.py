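"""Anchor an ordered gene list to the map and list genes under an MQTL CI.

The syntenome carries gene order, not positions; backbone markers shared
with the consensus map carry both an ordinal slot and a cM position, so
gene positions are interpolated in ordinal rank between flanking markers.
"""

from mqtlkit import anchor_syntenome, genes_in_interval
from mqtlkit.simulate import simulate_maps, simulate_syntenome

true_map, _, _ = simulate_maps(
    n_maps=1, chromosomes=[("5A", 120.0)], markers_per_chrom=12,
    share_frac=1.0, distortion_sd=0.0, seed=3,
)
genes, backbone = simulate_syntenome(true_map, genes_per_interval=3, seed=3)
anchored = anchor_syntenome(genes, backbone)

interval = (30.0, 55.0)  # an MQTL 95% confidence interval in consensus cM
repertoire = genes_in_interval(anchored, "5A", interval)
print(f"{len(genes)} ordered genes, {len(backbone)} backbone anchors on 5A")
print(f"genes under MQTL CI [{interval[0]}, {interval[1]}] cM: {len(repertoire)}")
print(repertoire[["gene_id", "ordinal", "anchored_cM"]].head(8).to_string(index=False))
# Every listed gene has an interpolated position inside the closed interval;
# nested intervals always yield nested repertoires.
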