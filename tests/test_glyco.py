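"""GlyCo grouping at the 5-nm cut-off and class-table construction."""

import numpy as np
import pandas as pd
import pytest

from glycoatlas.core import BindingSiteSet
from glycoatlas.errors import ParameterError
from glycoatlas.glyco import class_map, classify_groups, group_sites, top_classes

from conftest import brute_force_components


def sites(label, xy):
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return BindingSiteSet(
        label,
        pd.DataFrame(
            {"x_nm": xy[:, 0], "y_nm": xy[:, 1], "n_locs": 2, "first_frame": 0, "last_frame": 1}
        ),
    )


class TestGrouping:
    def test_close_pair_groups(self):
        groups = group_sites([sites("WGA", [[0, 0]]), sites("SNA", [[3, 0]])], 5.0)
        assert sorted(g.size for g in groups) == [2]
        assert groups[0].label == "SNA+WGA"

    def test_distant_pair_stays_singletons(self):
        groups = group_sites([sites("WGA", [[0, 0]]), sites("SNA", [[6, 0]])], 5.0)
        assert sorted(g.size for g in groups) == [1, 1]

    def test_chain_closure(self):
        """Five sites at 4-nm spacing merge transitively into one group."""
        chain = [[i * 4.0, 0.0] for i in range(5)]
        panel = [sites("W", [chain[0], chain[2]]), sites("S", [chain[1]]),
                 sites("A", [chain[3]]), sites("P", [chain[4]])]
        groups = group_sites(panel, 5.0)
        assert [g.size for g in groups] == [5]
        assert groups[0].label == "A+P+S+W+W"

    def test_matches_brute_force_union_find(self, rng):
        xy = rng.uniform(0, 400, size=(300, 2))
        panel = [sites("A", xy[:150]), sites("B", xy[150:])]
        groups = group_sites(panel, 10.0)
        ours = {frozenset(map(tuple, g.xy)) for g in groups}
        oracle = {
            frozenset(tuple(xy[i]) for i in c) for c in brute_force_components(xy, 10.0)
        }
        assert ours == oracle

    def test_monotone_in_cutoff(self, rng):
        xy = rng.uniform(0, 200, size=(120, 2))
        panel = [sites("A", xy)]
        n_prev = None
        for cut in (1.0, 5.0, 20.0, 80.0):
            n = len(group_sites(panel, cut))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_vanishing_cutoff_gives_singletons(self, rng):
        xy = rng.uniform(0, 1000, size=(50, 2))
        groups = group_sites([sites("A", xy)], 1e-9)
        assert all(g.size == 1 for g in groups)
        table = classify_groups(groups, 1.0)
        assert len(table.classes) == 0
        assert table.n_singletons == 50

    def test_channel_permutation_invariance(self, rng):
        """Relabelling channels permutes class labels, preserves counts."""
        xy1, xy2 = rng.uniform(0, 300, size=(40, 2)), rng.uniform(0, 300, size=(40, 2))
        t1 = classify_groups(group_sites([sites("A", xy1), sites("B", xy2)], 8.0), 1.0)
        t2 = classify_groups(group_sites([sites("B", xy1), sites("A", xy2)], 8.0), 1.0)
        c1 = sorted(t1.classes["count"])
        c2 = sorted(t2.classes["count"])
        assert c1 == c2
        assert t1.n_singletons == t2.n_singletons


class TestClassification:
    def panel(self):
        # groups: {W,S} at x=0, {S,W} at x=100, {W,W} at x=200
        w = sites("WGA", [[0, 0], [100, 0], [200, 0], [202, 0]])
        s = sites("SNA", [[3, 0], [103, 0]])
        return [w, s]

    def test_canonical_labels_counts_densities(self):
        table = classify_groups(group_sites(self.panel(), 5.0), roi_area_um2=2.0)
        by = {r["label"]: r for _, r in table.classes.iterrows()}
        assert by["SNA+WGA"]["count"] == 2
        assert by["SNA+WGA"]["density_per_um2"] == pytest.approx(1.0)
        assert by["WGA+WGA"]["count"] == 1
        assert by["WGA+WGA"]["density_per_um2"] == pytest.approx(0.5)

    def test_site_conservation(self):
        table = classify_groups(group_sites(self.panel(), 5.0), 2.0)
        total = (table.classes["count"] * table.classes["size"]).sum() + table.n_singletons
        assert total == table.n_sites_total == 6

    def test_only_singletons_empty_table(self, rng):
        xy = rng.uniform(0, 10_000, size=(30, 2))
        table = classify_groups(group_sites([sites("A", xy)], 5.0), 1.0)
        assert len(table.classes) == 0
        assert table.n_singletons == 30

    def test_zero_area_rejected(self):
        with pytest.raises(ParameterError):
            classify_groups([], 0.0)


class TestTopClasses:
    def table_with_counts(self, counts: dict):
        rows = [
            {"label": k, "size": 2, "count": v, "density_per_um2": float(v)}
            for k, v in counts.items()
        ]
        from glycoatlas.glyco import GlycoClassTable

        return GlycoClassTable(pd.DataFrame(rows), pd.DataFrame(
            columns=["label", "size", "centroid_x_nm", "centroid_y_nm", "member_channels"]
        ), 1.0, 0, 0)

    def test_count_then_lexicographic(self):
        t = self.table_with_counts({"A+B": 5, "B+C": 3, "A+C": 3})
        top = top_classes(t, 2)
        assert list(top["label"]) == ["A+B", "A+C"]

    def test_n_larger_than_available(self):
        t = self.table_with_counts({"A+B": 1})
        assert len(top_classes(t, 10)) == 1

    def test_order_equals_sort_oracle(self, rng):
        counts = {f"C{i}+D{i}": int(c) for i, c in enumerate(rng.integers(1, 20, 30))}
        t = self.table_with_counts(counts)
        top = top_classes(t, 30)
        oracle = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        assert list(top["label"]) == [k for k, _ in oracle]


class TestClassMap:
    def test_single_instance_layer(self):
        table = classify_groups(
            group_sites([sites("A", [[0, 0]]), sites("B", [[2, 0]])], 5.0), 1.0
        )
        layers = class_map(table)
        assert list(layers) == ["A+B"]
        np.testing.assert_allclose(layers["A+B"], [[1.0, 0.0]])

    def test_layers_partition_instances(self, rng):
        xy = rng.uniform(0, 500, size=(100, 2))
        table = classify_groups(group_sites([sites("A", xy[:50]), sites("B", xy[50:])], 12.0), 1.0)
        layers = class_map(table)
        assert sum(len(v) for v in layers.values()) == table.classes["count"].sum()

    def test_planted_spatial_segregation_preserved(self, rng):
        """Classes planted left vs right keep separated centroid x-means."""
        left = np.c_[rng.uniform(0, 100, 20), rng.uniform(0, 1000, 20)]
        right = np.c_[rng.uniform(900, 1000, 20), rng.uniform(0, 1000, 20)]
        a = sites("A", np.vstack([left, right]))
        b = sites("B", np.vstack([left + [2, 0], right + [2, 0]]))
        # left pairs A+B; right pairs also A+B -> same class; instead tag right with C
        c = sites("C", right + [2, 0])
        table = classify_groups(group_sites([a, b, c], 5.0), 1.0)
        layers = class_map(table)
        assert layers["A+B"][:, 0].mean() < 200
        assert layers["A+B+C"][:, 0].mean() > 800
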