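"""Genetic map reading, consistency checking, projection and merging."""

import numpy as np
import pandas as pd
import pytest
from conftest import brute_force_max_monotone, make_map
from hypothesis import given, settings
from hypothesis import strategies as st

from mqtlkit import (
    AnchorFrame,
    GeneticMap,
    MapFormatError,
    ProjectionError,
    ValidationError,
    check_order_consistency,
    merge_maps,
    project_position,
    read_map,
    summarize_map,
)


class TestReadMap:
    def test_well_formed_file(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "chromosome\tmarker\tposition_cM\tmarker_type\n"
            "1A\tm1\t0.0\tSNP\n1A\tm2\t12.5\tSSR\n2B\tm3\t3.0\tSNP\n"
        )
        gmap = read_map(p, "m")
        assert len(gmap) == 3
        assert gmap.chromosomes == ["1A", "2B"]
        assert gmap.positions("1A").to_dict() == {"m1": 0.0, "m2": 12.5}

    def test_header_only_gives_empty_map(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chromosome\tmarker\tposition_cM\tmarker_type\n")
        assert len(read_map(p, "m")) == 0

    def test_negative_position_cites_line(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "chromosome\tmarker\tposition_cM\tmarker_type\n"
            "1A\tm1\t1.0\tSNP\n1A\tm2\t-5.0\tSNP\n"
        )
        with pytest.raises(ValidationError, match="line 3"):
            read_map(p, "m")

    def test_missing_column(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chromosome\tmarker\tmarker_type\n1A\tm1\tSNP\n")
        with pytest.raises(MapFormatError, match="position_cM"):
            read_map(p, "m")

    def test_duplicate_marker_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "chromosome\tmarker\tposition_cM\tmarker_type\n"
            "1A\tm1\t1.0\tSNP\n1A\tm1\t2.0\tSNP\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_map(p, "m")

    def test_roundtrip_two_decimals(self, tmp_path, simple_map):
        p = tmp_path / "out.tsv"
        simple_map.to_tsv(p)
        again = read_map(p, "A")
        assert simple_map.equals(again)


class TestOrderConsistency:
    def test_identical_order_keeps_everything(self):
        items = [(f"m{i}", float(i)) for i in range(10)]
        a = make_map("A", {"1A": items})
        b = make_map("B", {"1A": [(n, 2 * p + 1) for n, p in items]})
        rep = check_order_consistency(a, b)
        assert rep.conflicts == []
        assert rep.retained["1A"] == [f"m{i}" for i in range(10)]

    def test_single_swap_flags_one_marker(self):
        a = make_map("A", {"1A": [(n, float(i)) for i, n in enumerate("ABCDE")]})
        b = make_map("B", {"1A": [(n, float(i)) for i, n in enumerate("ABDCE")]})
        rep = check_order_consistency(a, b)
        flagged = rep.conflicted_names()
        assert len(flagged) == 1 and flagged <= {"C", "D"}
        assert len(rep.retained["1A"]) == 4

    def test_chromosome_assignment_conflict(self):
        a = make_map("A", {"1A": [("x", 5.0), ("k1", 0.0), ("k2", 10.0)]})
        b = make_map("B", {"1B": [("x", 5.0)], "1A": [("k1", 0.0), ("k2", 10.0)]})
        rep = check_order_consistency(a, b)
        (c,) = [c for c in rep.conflicts if c.marker == "x"]
        assert c.reason == "chromosome_assignment"
        assert c.chromosome_a == "1A" and c.chromosome_b == "1B"

    def test_no_shared_markers_empty_report(self):
        a = make_map("A", {"1A": [("m1", 0.0)]})
        b = make_map("B", {"1A": [("z1", 0.0)]})
        rep = check_order_consistency(a, b)
        assert rep.conflicts == [] and rep.retained == {}

    @given(st.lists(st.integers(0, 9), min_size=1, max_size=9))
    @settings(max_examples=60, deadline=None)
    def test_retained_matches_brute_force_maximum(self, ranks):
        """Retained cardinality equals the exhaustive max common monotone subsequence."""
        a = make_map("A", {"1A": [(f"m{i}", float(i)) for i in range(len(ranks))]})
        b = make_map("B", {"1A": [(f"m{i}", float(r) + 0.1 * i) for i, r in enumerate(ranks)]})
        rep = check_order_consistency(a, b)
        assert len(rep.retained["1A"]) == brute_force_max_monotone(
            [float(r) + 0.1 * i for i, r in enumerate(ranks)]
        )


class TestProjection:
    def test_identity_frame(self):
        frame = AnchorFrame([(0, 0), (10, 10)])
        assert project_position(4.0, frame) == pytest.approx(4.0)

    def test_pure_scaling(self):
        frame = AnchorFrame([(0, 0), (10, 20)])
        assert project_position(5.0, frame) == pytest.approx(10.0)

    def test_piecewise_interior(self):
        frame = AnchorFrame([(0, 0), (10, 15), (30, 30)])
        assert project_position(20.0, frame) == pytest.approx(22.5)

    def test_anchor_fixpoints(self):
        frame = AnchorFrame([(2, 7), (10, 15), (30, 31)])
        for s, d in zip(frame.src, frame.dst):
            assert project_position(float(s), frame) == pytest.approx(float(d))

    def test_extrapolation_extends_terminal_scale(self):
        frame = AnchorFrame([(10, 20), (20, 40)])  # scale x2 on both ends
        assert project_position(5.0, frame) == pytest.approx(10.0)
        assert project_position(25.0, frame) == pytest.approx(50.0)

    def test_zero_length_terminal_destination_uses_unit_scale(self):
        frame = AnchorFrame([(0, 5), (10, 5), (20, 15)])
        assert project_position(-2.0, frame) == pytest.approx(3.0)

    def test_tied_source_anchors_collapse_to_mean(self):
        frame = AnchorFrame([(0, 0), (10, 12), (10, 18), (20, 20)])
        assert frame.n_anchors == 3
        assert project_position(10.0, frame) == pytest.approx(15.0)

    def test_single_anchor_rejected(self):
        frame = AnchorFrame([(0, 3)])
        with pytest.raises(ProjectionError):
            project_position(1.0, frame)

    def test_decreasing_destinations_rejected(self):
        with pytest.raises(ProjectionError):
            AnchorFrame([(0, 10), (10, 5)])

    @given(
        st.lists(
            st.tuples(st.floats(0, 200), st.floats(0, 200)),
            min_size=2,
            max_size=8,
            unique_by=lambda t: round(t[0], 3),
        ),
        st.lists(st.floats(-20, 220), min_size=2, max_size=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_nondecreasing(self, pairs, points):
        """p1 <= p2 implies project(p1) <= project(p2) for any valid frame."""
        src = sorted(p[0] for p in pairs)
        dst = sorted(p[1] for p in pairs)
        frame = AnchorFrame(list(zip(src, dst)))
        pts = np.sort(np.array(points))
        out = project_position(pts, frame)
        assert np.all(np.diff(out) >= -1e-9)


class TestMerge:
    def test_self_merge_idempotent(self, simple_map):
        res = merge_maps([simple_map, simple_map])
        assert res.consensus.equals(simple_map)
        assert res.conflicts == [] and len(res.unplaced) == 0

    def test_unique_marker_projected_homothetically(self, simple_map):
        second = make_map(
            "B", {"1A": [("m1", 0.0), ("m2", 5.0), ("m3", 10.0), ("u1", 7.5)]}
        )
        res = merge_maps([simple_map, second])
        pos = res.consensus.positions("1A")
        assert pos["u1"] == pytest.approx(15.0)  # second interval scale x2
        assert len(res.consensus) == 4

    def test_single_shared_anchor_blocks_projection(self, simple_map):
        second = make_map("B", {"1A": [("m1", 3.0), ("u1", 9.0)]})
        res = merge_maps([simple_map, second])
        assert "u1" not in set(res.consensus.frame["marker"])
        assert res.unplaced.iloc[0]["marker"] == "u1"
        assert "anchor" in res.unplaced.iloc[0]["reason"]

    def test_conservation_of_marker_counts(self, rng):
        maps = []
        for j in range(3):
            names = [f"m{i}" for i in range(20)]
            pos = np.sort(rng.uniform(0, 100, 20))
            maps.append(make_map(f"M{j}", {"1A": list(zip(names, pos + j))}))
        res = merge_maps(maps)
        # all maps share all names: consensus must equal the backbone exactly
        n_unique_nonconflicted = 0
        assert len(res.consensus) == len(maps[0]) + n_unique_nonconflicted

    def test_by_size_uses_densest_backbone(self):
        small = make_map("S", {"1A": [("a", 0.0), ("b", 5.0)]})
        big = make_map(
            "B", {"1A": [("a", 0.0), ("b", 50.0), ("c", 70.0)]}
        )
        res = merge_maps([small, big], order="by-size")
        assert res.consensus.positions("1A")["b"] == 50.0  # big map's coordinates kept

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            merge_maps([])

    def test_conflicted_marker_kept_in_consensus_dropped_from_incoming(self):
        a = make_map("A", {"1A": [(n, float(i)) for i, n in enumerate("ABCDE")]})
        b = make_map("B", {"1A": [("A", 0.0), ("B", 1.0), ("D", 1.5), ("C", 2.0), ("E", 4.0)]})
        res = merge_maps([a, b])
        pos = res.consensus.positions("1A")
        assert set(pos.index) == set("ABCDE")  # consensus retains everything
        assert pos["C"] == 2.0 and pos["D"] == 3.0  # at backbone coordinates


class TestSummaries:
    def test_empty_map_zero_counts(self):
        empty = GeneticMap("E", pd.DataFrame(columns=GeneticMap.COLUMNS))
        assert summarize_map(empty, "grand_total")["grand_total"].iloc[0] == 0
        grp = summarize_map(empty, "homoeologous_group")
        assert grp["n_markers"].sum() == 0

    def test_group_and_type_sums_equal_grand_total(self):
        rows = []
        for chrom in ["1A", "2B", "7D"]:
            for i in range(5):
                rows.append(
                    {
                        "chromosome": chrom,
                        "marker": f"{chrom}_{i}",
                        "position_cM": float(i),
                        "marker_type": ["SNP", "SSR"][i % 2],
                    }
                )
        gmap = GeneticMap("G", pd.DataFrame(rows))
        total = summarize_map(gmap, "grand_total")["grand_total"].iloc[0]
        by_group = summarize_map(gmap, "homoeologous_group")["n_markers"].sum()
        by_sub = summarize_map(gmap, "subgenome")["n_markers"].sum()
        tab = summarize_map(gmap, "chromosome_by_type")
        assert total == by_group == by_sub == 15
        assert tab.loc["Total", "Total"] == 15

    def test_wheat_grouping_rejects_foreign_labels(self):
        gmap = make_map("G", {"chrX": [("m", 1.0)]})
        with pytest.raises(ValidationError):
            summarize_map(gmap, "subgenome")
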