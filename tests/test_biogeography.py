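"""dCORT dissimilarity, clustering, Köppen rules and region delimitation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleocoex.biogeography import (
    DcortConfig,
    cluster_npp,
    dcort_distance,
    delimit_regions,
    dissimilarity_matrix,
    jaccard_dissimilarity,
    koppen_classify,
)
from paleocoex.npp import NPPSeries


def _series(sid, values):
    t = np.arange(55.0, 55.0 - len(values) * 0.5, -0.5)
    return NPPSeries(sid, t, np.asarray(values, dtype=float))


class TestDcort:
    def test_identical_series_zero(self):
        s = _series("a", [0.1, 0.2, 0.3, 0.25])
        assert dcort_distance(s, s) == 0.0

    def test_hand_computed_example(self):
        # opposite trends: CORT = -1, phi_2(-1) = 2/(1+e^-2), d = sqrt(8)
        a = _series("a", [0.0, 1.0, 2.0])
        b = _series("b", [2.0, 1.0, 0.0])
        d = dcort_distance(a, b, DcortConfig(k_tuning=2.0))
        phi = 2.0 / (1.0 + np.exp(-2.0))
        expected = phi * np.sqrt(4.0 + 0.0 + 4.0)
        assert d == pytest.approx(expected, rel=1e-12)

    def test_orthogonal_increments_reduce_to_euclidean(self):
        a = _series("a", [1.0, 2.0, 1.0, 2.0, 1.0])
        b = _series("b", [3.0, 4.0, 5.0, 6.0, 7.0])
        d1 = np.diff(a.values) @ np.diff(b.values)
        assert d1 == pytest.approx(0.0)
        d = dcort_distance(a, b, DcortConfig(k_tuning=2.0))
        assert d == pytest.approx(np.linalg.norm(a.values - b.values))

    def test_k_zero_is_plain_euclidean(self):
        a = _series("a", [1.0, 2.0, 3.0])
        b = _series("b", [2.0, 1.5, 1.0])
        assert dcort_distance(a, b, DcortConfig(k_tuning=0.0)) == pytest.approx(
            np.linalg.norm(a.values - b.values)
        )

    def test_symmetry(self):
        a = _series("a", [1.0, 2.0, 1.5, 2.5])
        b = _series("b", [0.5, 0.7, 1.8, 0.2])
        assert dcort_distance(a, b) == pytest.approx(dcort_distance(b, a))

    def test_mismatched_grids_rejected(self):
        a = _series("a", [1.0, 2.0, 3.0])
        b = NPPSeries("b", np.array([50.0, 49.0, 48.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="identical time grid"):
            dcort_distance(a, b)


class TestClusterNPP:
    def _two_group_series(self):
        rng = np.random.default_rng(0)
        series = {}
        for i in range(5):
            series[f"a{i}"] = _series(f"a{i}", 1.0 + 0.01 * rng.random(20))
            series[f"b{i}"] = _series(f"b{i}", 5.0 + 0.01 * rng.random(20))
        return series

    def test_planted_partition_recovered(self):
        mat = dissimilarity_matrix(self._two_group_series())
        labels = cluster_npp(mat, n_clusters=2)
        a_labels = {labels[k] for k in labels.index if k.startswith("a")}
        b_labels = {labels[k] for k in labels.index if k.startswith("b")}
        assert len(a_labels) == 1 and len(b_labels) == 1
        assert a_labels != b_labels

    def test_gap_rule_finds_two_clusters(self):
        mat = dissimilarity_matrix(self._two_group_series())
        labels = cluster_npp(mat)  # automatic cut
        assert labels.nunique() == 2

    def test_singletons_when_k_equals_n(self):
        mat = dissimilarity_matrix(self._two_group_series())
        labels = cluster_npp(mat, n_clusters=len(mat))
        assert labels.nunique() == len(mat)

    def test_permutation_invariance(self):
        mat = dissimilarity_matrix(self._two_group_series())
        perm = list(mat.index)[::-1]
        labels1 = cluster_npp(mat, n_clusters=2)
        labels2 = cluster_npp(mat.loc[perm, perm], n_clusters=2)
        # same partition: co-membership must agree for every pair
        for x in mat.index:
            for y in mat.index:
                assert (labels1[x] == labels1[y]) == (labels2[x] == labels2[y])

    def test_too_many_clusters_rejected(self):
        mat = dissimilarity_matrix(self._two_group_series())
        with pytest.raises(ValueError, match="more clusters"):
            cluster_npp(mat, n_clusters=len(mat) + 1)


class TestKoppen:
    def test_tundra(self):
        t = np.full(12, -20.0)
        t[6] = 8.0
        assert koppen_classify(t, np.full(12, 50.0)) == "ET"

    def test_frost(self):
        t = np.full(12, -25.0)
        t[6] = -1.0
        assert koppen_classify(t, np.full(12, 30.0)) == "EF"

    def test_dfa_boundary_at_22(self):
        t = np.array([-5.0, -4, 0, 6, 12, 18, 22, 21, 16, 9, 2, -3])
        assert koppen_classify(t, np.full(12, 60.0)) == "Dfa"

    def test_dfb_below_boundary(self):
        t = np.array([-5.0, -4, 0, 6, 12, 18, 21.9, 21, 16, 9, 2, -3])
        assert koppen_classify(t, np.full(12, 60.0)) == "Dfb"

    def test_csa_dry_summer(self):
        t = np.array([2.0, 3, 6, 10, 15, 20, 24, 23, 19, 13, 7, 3])
        p = np.array([90.0, 80, 70, 40, 25, 12, 5, 8, 30, 70, 90, 95.0])
        assert koppen_classify(t, p) == "Csa"

    def test_cold_summer_modifier(self):
        t = np.array([-8.0, -7, -4, 1, 6, 10, 12, 11, 7, 2, -3, -6])
        assert koppen_classify(t, np.full(12, 50.0)) == "Dfc"

    def test_nonphysical_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-physical"):
            koppen_classify(np.full(12, -100.0), np.full(12, 10.0))
        with pytest.raises(ValueError, match="non-physical"):
            koppen_classify(np.full(12, 5.0), np.full(12, -1.0))


class TestJaccard:
    def test_examples(self):
        assert jaccard_dissimilarity({"a", "b"}, {"a", "b"}) == 0.0
        assert jaccard_dissimilarity({"a"}, {"b"}) == 1.0
        assert jaccard_dissimilarity({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)
        assert jaccard_dissimilarity(set(), set()) == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 8), max_size=8),
        b=st.sets(st.integers(0, 8), max_size=8),
        c=st.sets(st.integers(0, 8), max_size=8),
    )
    def test_bounded_and_triangle_inequality(self, a, b, c):
        dab = jaccard_dissimilarity(a, b)
        assert 0.0 <= dab <= 1.0
        assert dab <= jaccard_dissimilarity(a, c) + jaccard_dissimilarity(c, b) + 1e-12


class TestDelimitRegions:
    def _inputs(self, npp, climate, fauna, lons):
        sites = [f"s{i}" for i in range(len(npp))]
        return (
            pd.Series(npp, index=sites),
            pd.Series(climate, index=sites),
            pd.Series(fauna, index=sites),
            pd.Series(lons, index=sites),
        )

    def test_homogeneous_labels_one_region(self):
        labels, regions = delimit_regions(
            *self._inputs([1, 1, 1], ["Dfc"] * 3, [1, 1, 1], [5.0, 6.0, 7.0])
        )
        assert labels.nunique() == 1
        assert regions[0].region_id == "R_1"

    def test_climate_split_inside_npp_cluster(self):
        labels, _ = delimit_regions(
            *self._inputs([1, 1, 1, 1], ["Dfc", "Dfc", "Cfb", "Cfb"], [1] * 4,
                          [5.0, 6.0, 7.0, 8.0])
        )
        assert labels.nunique() == 2

    def test_refinement_count(self):
        # 3 NPP clusters, a fauna split inside one of them -> 4 regions
        labels, _ = delimit_regions(
            *self._inputs(
                [1, 1, 2, 2, 3, 3],
                ["Dfc"] * 6,
                [1, 2, 1, 1, 1, 1],
                [10.0, 11.0, 5.0, 6.0, 0.0, 1.0],
            )
        )
        assert labels.nunique() == 4

    def test_partition_refines_npp_clusters(self):
        npp = [1, 1, 2, 2, 2, 3]
        labels, _ = delimit_regions(
            *self._inputs(
                npp,
                ["Dfc", "Cfb", "Dfc", "Dfc", "Cfb", "Dfc"],
                [1, 1, 1, 2, 1, 1],
                [3.0, 2.0, 8.0, 9.0, 10.0, -4.0],
            )
        )
        # never merge two NPP clusters into one region
        npp_of = dict(zip(labels.index, npp))
        for region in labels.unique():
            members = labels[labels == region].index
            assert len({npp_of[m] for m in members}) == 1

    def test_east_west_ordering(self):
        labels, regions = delimit_regions(
            *self._inputs([1, 1, 2, 2], ["Dfc"] * 4, [1] * 4, [20.0, 21.0, -5.0, -6.0])
        )
        by_id = {r.region_id: r for r in regions}
        assert by_id["R_1"].mean_longitude > by_id["R_2"].mean_longitude

    def test_uncovered_site_rejected(self):
        npp, climate, fauna, lons = self._inputs([1, 1], ["Dfc"] * 2, [1, 1], [0.0, 1.0])
        with pytest.raises(ValueError, match="same site set"):
            delimit_regions(npp, climate.iloc[:1], fauna, lons)
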