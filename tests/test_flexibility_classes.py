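import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vhhdyn.flexibility_classes import (FLEX_LABELS, classify,
                                        classify_profile, cluster_profiles,
                                        termini_distance, termini_table)
from vhhdyn.io_formats import MSA, RegionConfig
from vhhdyn.msa_projection import build_alignment_map
from vhhdyn.synthetic import build_backbone, gen_ensemble3d

from conftest import make_ensemble


class TestClassify:
    @pytest.mark.parametrize("rmsf_norm,neq,expected", [
        (2.5, 3.5, "flexible"),
        (2.5, 2.9, "mobile"),
        (2.0, 3.0, "rigid"),      # strict inequalities at both thresholds
        (1.0, 3.5, "deformable"),
        (2.5, 3.0, "mobile"),     # exactly at the Neq threshold
        (-1.0, 1.0, "rigid"),
    ])
    def test_quadrants(self, rmsf_norm, neq, expected):
        assert classify(rmsf_norm, neq) == expected

    def test_undefined_inputs_propagate(self):
        assert classify(float("nan"), 2.0) is None
        labels = classify_profile([1.0, np.nan], [5.0, 2.0])
        assert labels[0] == "deformable" and labels[1] == ""

    def test_custom_thresholds(self):
        cfg = RegionConfig(rmsf_threshold=1.0, neq_threshold=1.5)
        assert classify(1.2, 1.6, cfg) == "flexible"

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-5, 5, allow_nan=False),
           st.floats(1, 16, allow_nan=False))
    def test_partition_of_the_plane(self, r, n):
        assert classify(r, n) in FLEX_LABELS


class TestClusterProfiles:
    def setup_counts(self):
        msa = MSA(sequences={"a": "AD", "b": "AD", "c": "GD"})
        amap = build_alignment_map(msa)
        # column 1: a,b all block d; c all block m
        counts = {
            "a": np.array([[0.0] * 3 + [10.0] + [0.0] * 12,
                           [0.0] * 16]),
            "b": np.array([[0.0] * 3 + [10.0] + [0.0] * 12,
                           [0.0] * 16]),
            "c": np.array([[0.0] * 12 + [10.0] + [0.0] * 3,
                           [0.0] * 16]),
        }
        # reorder: block d is index 3, block m is index 12
        counts["c"][0] = 0.0
        counts["c"][0, 12] = 10.0
        return msa, amap, counts

    def test_full_dataset_gives_zero_profiles(self):
        msa, amap, counts = self.setup_counts()
        out = cluster_profiles(["a", "b", "c"], counts, msa, amap)
        assert np.allclose(out["delta_pb"].dropna(), 0.0)
        assert np.allclose(out["delta_aa"].dropna(), 0.0)

    def test_hand_computed_deviation(self):
        msa = MSA(sequences={"a": "A", "b": "A"})
        amap = build_alignment_map(msa)
        counts = {
            "a": np.array([[0.0] * 3 + [10.0] + [0.0] * 12]),
            "b": np.array([[0.0] * 12 + [10.0] + [0.0] * 3]),
        }
        out = cluster_profiles(["a"], counts, msa, amap)
        # cluster all-d vs dataset half d half m
        assert out["delta_pb"].iloc[0] == pytest.approx(1.0)

    def test_single_member_cluster_and_bounds(self):
        msa, amap, counts = self.setup_counts()
        out = cluster_profiles(["c"], counts, msa, amap)
        assert (out["delta_pb"].dropna() <= 2.0 + 1e-12).all()
        # c is all-m at column 1, dataset is 2/3 d + 1/3 m
        assert out["delta_pb"].iloc[0] == pytest.approx(4 / 3)
        assert out["delta_aa"].iloc[0] == pytest.approx(4 / 3)

    def test_empty_cluster_rejected(self):
        msa, amap, counts = self.setup_counts()
        with pytest.raises(ValueError):
            cluster_profiles([], counts, msa, amap)

    def test_foreign_member_rejected(self):
        msa, amap, counts = self.setup_counts()
        with pytest.raises(ValueError):
            cluster_profiles(["zz"], counts, msa, amap)


class TestTermini:
    def make_domain(self, coords, seq):
        msa = MSA(sequences={"dom": seq})
        amap = build_alignment_map(msa)
        ens = make_ensemble(coords, residues=seq.replace("-", ""))
        return ens, amap

    def test_three_four_five_distance(self):
        coords = np.zeros((3, 2, 3, 3))
        coords[:, 1, 1] = (3.0, 4.0, 0.0)
        ens, amap = self.make_domain(coords, "AA")
        st = termini_distance(ens, amap, (1, 2), "CDR1")
        assert st.mean == pytest.approx(5.0)
        assert st.sd == pytest.approx(0.0)

    def test_two_frame_mean_and_sd(self):
        coords = np.zeros((2, 2, 3, 3))
        coords[0, 1, 1] = (4.0, 0.0, 0.0)
        coords[1, 1, 1] = (6.0, 0.0, 0.0)
        ens, amap = self.make_domain(coords, "AA")
        st = termini_distance(ens, amap, (1, 2))
        assert st.mean == pytest.approx(5.0)
        assert st.sd == pytest.approx(1.0)

    def test_gap_boundary_uses_first_occupied_column(self):
        # interval 1-3 but column 1 is a gap: termini are columns 2 and 3
        coords = np.zeros((1, 2, 3, 3))
        coords[0, 1, 1] = (0.0, 7.0, 0.0)
        ens, amap = self.make_domain(coords, "-AA")
        st = termini_distance(ens, amap, (1, 3))
        assert st.mean == pytest.approx(7.0)

    def test_unoccupied_interval_flagged_missing(self):
        coords = np.zeros((1, 2, 3, 3))
        coords[0, 1, 1] = (1.0, 0.0, 0.0)
        ens, amap = self.make_domain(coords, "AA--")
        assert termini_distance(ens, amap, (3, 4)) is None

    def test_invariance_under_rigid_motion(self, rng):
        base = build_backbone(np.tile([-120.0, 135.0], (8, 1)),
                              domain_id="dom")
        ens = gen_ensemble3d(base, 0.4, n_frames=20, seed=1)
        msa = MSA(sequences={"dom": ens.residues})
        amap = build_alignment_map(msa)
        st0 = termini_distance(ens, amap, (2, 7))
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=5).as_matrix()
        moved = make_ensemble(ens.coords @ R.T + np.array([3.0, -1.0, 8.0]),
                              residues=ens.residues)
        st1 = termini_distance(moved, amap, (2, 7))
        assert st1.mean == pytest.approx(st0.mean, abs=1e-9)
        assert st1.sd == pytest.approx(st0.sd, abs=1e-9)

    def test_sampled_distance_recovers_parameters(self):
        # CA pair separated by d0 with per-axis noise: mean within 3 SE
        rng = np.random.default_rng(11)
        n, d0, s = 4000, 12.0, 0.5
        coords = np.zeros((n, 2, 3, 3))
        coords[:, 1, 1, 0] = d0
        coords[:, 1, 1, :] += rng.normal(0, s, size=(n, 3))
        ens, amap = self.make_domain(coords, "AA")
        st = termini_distance(ens, amap, (1, 2))
        se = np.sqrt(3) * s / np.sqrt(n)
        assert abs(st.mean - np.sqrt(d0 ** 2 + 3 * s ** 2)) < 3 * se + 0.05

    def test_termini_table_covers_cdrs(self):
        coords = np.zeros((2, 4, 3, 3))
        coords[:, :, 1, 0] = np.arange(4) * 3.0
        msa = MSA(sequences={"dom": "AAAA"})
        amap = build_alignment_map(msa)
        ens = make_ensemble(coords, residues="AAAA", domain_id="dom")
        cfg = RegionConfig(regions={"FR1": (1, 1), "CDR1": (2, 4)})
        table = termini_table({"dom": ens}, amap, cfg)
        assert set(table["cdr"]) == {"CDR1"}
        assert table["mean_A"].iloc[0] == pytest.approx(6.0)
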