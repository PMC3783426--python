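"""Barcoding gap, 4x criterion, threshold clustering, depth-break scan."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eurydelim import delimit, distances, seqio
from eurydelim.delimit import Partition


def dm_from(values, ids=None):
    v = np.asarray(values, dtype=float)
    ids = tuple(ids or (f"s{i}" for i in range(len(v))))
    return distances.DistanceMatrix(ids, v)


def random_dm(rng, n):
    m = np.round(rng.random((n, n)) * 0.3, 4)
    v = np.triu(m, 1)
    return dm_from(v + v.T)


def random_partition(rng, ids, k=3):
    return Partition.from_dict({i: f"c{rng.integers(0, k)}" for i in ids})


class TestBarcodingGap:
    def test_gap_present_in_separated_data(self):
        v = np.array(
            [[0, 0.01, 0.2, 0.2], [0.01, 0, 0.2, 0.2], [0.2, 0.2, 0, 0.02], [0.2, 0.2, 0.02, 0]]
        )
        part = Partition.from_dict({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        rep = delimit.barcoding_gap(dm_from(v), part)
        assert rep.gap_present
        assert rep.gap_interval == (0.02, 0.2)

    def test_identical_sequences_no_gap(self):
        part = Partition.from_dict({"s0": "A", "s1": "A", "s2": "B"})
        rep = delimit.barcoding_gap(dm_from(np.zeros((3, 3))), part)
        assert rep.status == "absent"
        assert rep.max_intra == rep.min_inter == 0

    def test_all_singletons_undecidable(self):
        part = Partition.from_dict({"s0": "A", "s1": "B", "s2": "C"})
        rep = delimit.barcoding_gap(dm_from([[0, 1, 2], [1, 0, 3], [2, 3, 0]]), part)
        assert rep.status == "undecidable"

    def test_matches_pair_classification_oracle(self, rng):
        for _ in range(200):
            dm = random_dm(rng, int(rng.integers(4, 9)))
            part = random_partition(rng, dm.ids)
            if len(part.clades) < 2:
                continue
            rep = delimit.barcoding_gap(dm, part)
            intra, inter = [], []
            for i, j in itertools.combinations(range(len(dm.ids)), 2):
                same = part.clade_of(dm.ids[i]) == part.clade_of(dm.ids[j])
                (intra if same else inter).append(dm.values[i, j])
            if not intra:
                assert rep.status == "undecidable"
            else:
                assert rep.max_intra == pytest.approx(max(intra))
                assert rep.min_inter == pytest.approx(min(inter))
                assert rep.gap_present == (min(inter) > max(intra))


class TestFourX:
    def _two_clades(self, min_inter, max_intra):
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = max_intra
        v[2, 3] = v[3, 2] = max_intra
        for i in (0, 1):
            for j in (2, 3):
                v[i, j] = v[j, i] = min_inter
        return dm_from(v), Partition.from_dict(
            {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        )

    def test_ratio_five_passes(self):
        rep = delimit.four_x(*self._two_clades(0.05, 0.01))
        assert rep.global_pass
        assert rep.pairs[0]["ratio"] == pytest.approx(5.0)

    def test_ratio_exactly_four_fails(self):
        rep = delimit.four_x(*self._two_clades(0.04, 0.01))
        assert not rep.global_pass  # strict inequality

    def test_scale_invariance(self, rng):
        dm = random_dm(rng, 6)
        part = random_partition(rng, dm.ids, k=2)
        base = delimit.four_x(dm, part)
        scaled = delimit.four_x(
            distances.DistanceMatrix(dm.ids, dm.values * 7.3), part
        )
        assert [p["pass"] for p in base.pairs] == [p["pass"] for p in scaled.pairs]

    def test_singleton_clade_uses_zero_intra(self):
        v = np.array([[0, 0.1], [0.1, 0]])
        part = Partition.from_dict({"s0": "A", "s1": "B"})
        rep = delimit.four_x(dm_from(v), part)
        assert rep.pairs[0]["max_intra"] == 0
        assert rep.pairs[0]["pass"]

    def test_invariant_under_relabeling(self, rng):
        dm = random_dm(rng, 6)
        p1 = random_partition(rng, dm.ids, k=3)
        p2 = Partition.from_dict({i: "x" + c for i, c in p1.assignment})
        r1, r2 = delimit.four_x(dm, p1), delimit.four_x(dm, p2)
        assert r1.global_pass == r2.global_pass


class TestThresholdClusters:
    def test_zero_threshold_gives_singletons(self, rng):
        dm = random_dm(rng, 5)
        part = delimit.threshold_clusters(dm, 0.0)
        assert len(part.clades) == 5

    def test_large_threshold_gives_one_clade(self, rng):
        dm = random_dm(rng, 5)
        part = delimit.threshold_clusters(dm, float(dm.values.max()))
        assert len(part.clades) == 1

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 9))
            dm = random_dm(rng, n)
            t = float(rng.random() * 0.3)
            part = delimit.threshold_clusters(dm, t)
            # brute-force transitive closure
            adj = dm.values <= t
            reach = adj.copy()
            for k in range(n):
                reach = reach | (reach[:, [k]] & reach[[k], :])
            for i, j in itertools.combinations(range(n), 2):
                same = part.clade_of(dm.ids[i]) == part.clade_of(dm.ids[j])
                assert same == bool(reach[i, j])


class TestMergeCompare:
    def test_merge_reduces_clade_count(self):
        part = Partition.from_dict({"a": "Eg4", "b": "Eg5", "c": "Eg1"})
        merged = delimit.merge_clades(part, ["Eg4", "Eg5"])
        assert len(merged.clades) == 2

    def test_self_merge_is_identity(self):
        part = Partition.from_dict({"a": "X", "b": "Y"})
        merged = delimit.merge_clades(part, ["X"], new_label="X")
        assert merged.mapping == part.mapping

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            delimit.merge_clades(Partition.from_dict({"a": "X"}), ["nope"])

    def test_compare_equal_and_refinement(self):
        pa = Partition.from_dict({"a": "1", "b": "1", "c": "2"})
        pb = Partition.from_dict({"a": "x", "b": "x", "c": "y"})
        assert delimit.compare_partitions(pa, pb)["relation"] == "equal"
        pa2 = Partition.from_dict({"a": "1", "b": "2", "c": "3"})
        assert delimit.compare_partitions(pa2, pb)["relation"] == "a_refines_b"

    def test_compare_conflict_pairs_match_comembership_oracle(self, rng):
        ids = [f"s{i}" for i in range(7)]
        for _ in range(100):
            pa = random_partition(rng, ids)
            pb = random_partition(rng, ids)
            rep = delimit.compare_partitions(pa, pb)
            for x, y in itertools.combinations(sorted(ids), 2):
                sa = pa.clade_of(x) == pa.clade_of(y)
                sb = pb.clade_of(x) == pb.clade_of(y)
                assert ((x, y) in rep["pairs_split_only_in_b"]) == (sa and not sb)
                assert ((x, y) in rep["pairs_split_only_in_a"]) == (sb and not sa)

    def test_disjoint_partitions_rejected(self):
        with pytest.raises(ValueError):
            delimit.compare_partitions(
                Partition.from_dict({"a": "1"}), Partition.from_dict({"b": "1"})
            )


def meta_from(depths):
    rows = [{"id": k, "depth_m": v} for k, v in depths.items()]
    return seqio.SpecimenTable(pd.DataFrame(rows))


class TestDepthBreak:
    def test_clean_bathyal_abyssal_split(self):
        depths = {"a1": 800, "a2": 2743, "b1": 3070, "b2": 4693}
        part = Partition.from_dict({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        rep = delimit.depth_break(part, meta_from(depths))
        assert rep.break_found
        assert rep.interval == (2743, 3070)

    def test_spanning_clade_blocks_break(self):
        depths = {"a1": 2900, "a2": 3100, "b1": 800, "b2": 4500}
        part = Partition.from_dict({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        rep = delimit.depth_break(part, meta_from(depths))
        assert not any(2900 < t < 3100 and t not in rep.violations for t in rep.violations)
        assert rep.status == "no-break"

    def test_single_clade_degenerate(self):
        depths = {"a1": 1000, "a2": 2000}
        part = Partition.from_dict({"a1": "A", "a2": "A"})
        assert delimit.depth_break(part, meta_from(depths)).status == "degenerate"

    def test_row_order_invariance(self):
        depths = {"a1": 839, "a2": 2743, "b1": 3070, "b2": 4693, "c1": 3500}
        part = Partition.from_dict(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        )
        fwd = delimit.depth_break(part, meta_from(depths))
        rev = delimit.depth_break(
            part, meta_from(dict(reversed(list(depths.items()))))
        )
        assert fwd.interval == rev.interval and fwd.status == rev.status

    def test_missing_depth_excluded_with_warning(self):
        depths = {"a1": 800, "a2": None, "b1": 4000}
        part = Partition.from_dict({"a1": "A", "a2": "A", "b1": "B"})
        with pytest.warns(UserWarning, match="depth"):
            rep = delimit.depth_break(part, meta_from(depths))
        assert rep.break_found


class TestGapClusteringLink:
    def test_threshold_inside_gap_reproduces_partition(self, preset_dataset):
        """A present barcoding gap implies single-linkage clustering at any
        threshold inside it recovers the clade partition exactly."""
        from eurydelim import distances as dist

        aln = preset_dataset.alignments["COI"]
        dm = dist.distance_matrix(aln)
        part = preset_dataset.true_partition
        rep = delimit.barcoding_gap(dm, part)
        assert rep.gap_present
        lo, hi = rep.gap_interval
        for t in (lo + (hi - lo) * f for f in (0.25, 0.5, 0.75)):
            rec = delimit.threshold_clusters(dm, t)
            assert delimit.compare_partitions(rec, part)["relation"] == "equal"
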