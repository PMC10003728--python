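import numpy as np
import pytest

from vhhdyn.metrics import FrequencyVector, neq, rmsf
from vhhdyn.pb import (PB_LABELS, assign_ensemble, assign_window,
                       extract_dihedrals, rmsda)
from vhhdyn.pipeline import cluster_by_rmsf
from vhhdyn.synthetic import (FamilySpec, RegionSpec, WindowGeneratorSpec,
                              build_backbone, default_family_spec,
                              gen_ensemble3d, gen_family, gen_windows)
from sklearn.metrics import adjusted_rand_score


class TestGenWindows:
    def test_zero_noise_recovers_all_sixteen_labels(self, prototypes):
        spec = WindowGeneratorSpec(
            positions=[(l, None) for l in PB_LABELS],
            noise_sd=0.0, n_frames=5, seed=0)
        angles, labels = gen_windows(spec)
        for f in range(5):
            for p in range(16):
                assert assign_window(angles[f, p]) == labels[f, p]
        assert (labels == np.array(list(PB_LABELS))[None, :]).all()

    def test_seed_contract(self, prototypes):
        spec = WindowGeneratorSpec(positions=[("dm", None)] * 4,
                                   noise_sd=5.0, n_frames=50, seed=3)
        a1, l1 = gen_windows(spec)
        a2, l2 = gen_windows(spec)
        assert np.array_equal(a1, a2) and np.array_equal(l1, l2)
        spec2 = WindowGeneratorSpec(positions=[("dm", None)] * 4,
                                    noise_sd=5.0, n_frames=50, seed=4)
        a3, _ = gen_windows(spec2)
        assert not np.array_equal(a1, a3)

    def test_low_noise_mixture_neq_approaches_k(self, prototypes):
        # well-separated source blocks, noise far below half the minimum
        # pairwise prototype RMSDA (found by direct enumeration)
        pd = np.array([[rmsda(prototypes[i], prototypes[j])
                        for j in range(16)] for i in range(16)])
        np.fill_diagonal(pd, np.inf)
        sources = "dmgj"
        min_sep = pd.min()          # over the whole 16 x 16 table
        noise = min(3.0, min_sep / 10)
        spec = WindowGeneratorSpec(positions=[(sources, None)],
                                   noise_sd=noise, n_frames=2000, seed=5)
        angles, _ = gen_windows(spec)
        assigned = [assign_window(angles[f, 0]) for f in range(2000)]
        counts = np.array([assigned.count(l) for l in PB_LABELS], float)
        val = neq(FrequencyVector.from_counts(counts))
        assert val == pytest.approx(len(sources), abs=0.1)

    def test_weighted_sampling_respects_weights(self):
        spec = WindowGeneratorSpec(positions=[("dm", [0.9, 0.1])],
                                   noise_sd=0.0, n_frames=2000, seed=8)
        _, labels = gen_windows(spec)
        frac_d = (labels == "d").mean()
        assert abs(frac_d - 0.9) < 0.03

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowGeneratorSpec(positions=[("qz", None)])
        with pytest.raises(ValueError):
            WindowGeneratorSpec(positions=[("dm", [0.5])])
        with pytest.raises(ValueError):
            WindowGeneratorSpec(positions=[("d", None)], noise_sd=-1.0)


class TestBuildBackbone:
    def test_helical_round_trip(self):
        pp = np.tile([-57.0, -47.0], (10, 1))
        d = extract_dihedrals(build_backbone(pp))[0]
        assert np.abs(d[1:, 0] - (-57.0)).max() < 0.5
        assert np.abs(d[:-1, 1] - (-47.0)).max() < 0.5

    def test_three_residues_give_one_interior_pair(self):
        pp = np.tile([-120.0, 135.0], (3, 1))
        d = extract_dihedrals(build_backbone(pp))[0]
        defined = ~np.isnan(d)
        # one full (phi, psi) interior pair at residue 1
        assert defined[1].all()
        assert not defined[0, 0] and not defined[2, 1]

    def test_translation_leaves_dihedrals_unchanged(self):
        pp = np.tile([-75.0, 150.0], (6, 1))
        ens = build_backbone(pp)
        moved = build_backbone(pp)
        moved.coords = moved.coords + np.array([11.0, -4.0, 2.0])
        d0 = extract_dihedrals(ens)
        d1 = extract_dihedrals(moved)
        assert np.allclose(d0, d1, atol=1e-9, equal_nan=True)

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError):
            build_backbone(np.tile([-57.0, -47.0], (2, 1)))


class TestGenEnsemble3d:
    def test_zero_sigma_gives_zero_rmsf(self):
        base = build_backbone(np.tile([-120.0, 135.0], (6, 1)))
        ens = gen_ensemble3d(base, 0.0, n_frames=10, seed=0)
        assert np.allclose(rmsf(ens, fit=False).values, 0.0)

    def test_unit_sigma_matches_sqrt3_closed_form(self):
        base = build_backbone(np.tile([-120.0, 135.0], (10, 1)))
        n = 2000
        ens = gen_ensemble3d(base, 1.0, n_frames=n, seed=12)
        vals = rmsf(ens, fit=False).values
        # sd of a single-residue RMSF estimate is sigma / sqrt(2 n);
        # pooling the 10 independent residues divides it by sqrt(10)
        se = 1.0 / np.sqrt(2 * n * vals.size)
        assert abs(vals.mean() - np.sqrt(3.0)) < 3 * se

    def test_region_contrast_survives_normalisation(self):
        base = build_backbone(np.tile([-120.0, 135.0], (20, 1)))
        sigma = np.where(np.arange(20) < 10, 0.2, 1.0)
        ens = gen_ensemble3d(base, sigma, n_frames=300, seed=2)
        from vhhdyn.metrics import znormalise
        z = znormalise(rmsf(ens, fit=False).values)
        assert z[10:].min() > z[:10].max()

    def test_negative_sigma_rejected(self):
        base = build_backbone(np.tile([-120.0, 135.0], (5, 1)))
        with pytest.raises(ValueError):
            gen_ensemble3d(base, -0.1, n_frames=5)


class TestGenFamily:
    def test_determinism_and_seed_sensitivity(self):
        spec = default_family_spec(n_classes=2, domains_per_class=1,
                                   n_frames=20, seed=9)
        f1, f2 = gen_family(spec), gen_family(spec)
        d0 = next(iter(f1.ensembles))
        assert np.array_equal(f1.ensembles[d0].coords,
                              f2.ensembles[d0].coords)
        assert f1.msa.sequences == f2.msa.sequences
        spec_b = default_family_spec(n_classes=2, domains_per_class=1,
                                     n_frames=20, seed=10)
        f3 = gen_family(spec_b)
        assert not np.array_equal(f1.ensembles[d0].coords,
                                  f3.ensembles[d0].coords)

    def test_msa_matches_ensembles(self):
        spec = default_family_spec(n_classes=2, domains_per_class=2,
                                   n_frames=10, seed=3)
        fam = gen_family(spec)
        for did, ens in fam.ensembles.items():
            fam.msa.validate_against(ens)
        # gaps actually occur at the default gap rate
        assert any("-" in s for s in fam.msa.sequences.values())

    def test_gaps_avoid_region_cores(self):
        spec = default_family_spec(n_classes=1, domains_per_class=8,
                                   n_frames=5, seed=4, gap_rate=0.5)
        fam = gen_family(spec)
        for r in spec.regions:
            lo, hi = r.core()
            for seq in fam.msa.sequences.values():
                assert "-" not in seq[lo - 1:hi]

    def test_two_class_pipeline_recovery(self):
        spec = default_family_spec(n_classes=2, domains_per_class=4,
                                   n_frames=100, seed=6)
        fam = gen_family(spec)
        res = cluster_by_rmsf(fam.ensembles, fam.msa, k=2)
        truth = [fam.class_labels[d] for d in res.domain_ids]
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_within_class_distances_below_between_class(self,
                                                        family_four_class):
        from vhhdyn.clustering import profile_distance_matrix
        from vhhdyn.pipeline import rmsf_column_profiles
        fam = family_four_class
        profiles = rmsf_column_profiles(fam.ensembles, fam.msa)
        dm = profile_distance_matrix(profiles)
        labels = np.array([fam.class_labels[d] for d in dm.domain_ids])
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert dm.values[same & off].max() < dm.values[~same].min()

    def test_deformable_region_raises_neq_not_normalised_rmsf(self):
        # deformable is a *relative* notion: the domain also carries a
        # flexible loop, against which the deformable loop's z-scored
        # RMSF must stay below threshold while its Neq exceeds 3
        regions = [
            RegionSpec("fr1", 1, 20, ("rigid",)),
            RegionSpec("flex", 21, 27, ("flexible",)),
            RegionSpec("fr2", 28, 47, ("rigid",)),
            RegionSpec("def", 48, 54, ("deformable",)),
            RegionSpec("fr3", 55, 90, ("rigid",)),
        ]
        spec = FamilySpec(n_classes=1, domains_per_class=1, n_frames=500,
                          regions=regions, seed=5)
        fam = gen_family(spec)
        ens = next(iter(fam.ensembles.values()))
        pbm = assign_ensemble(extract_dihedrals(ens))
        from vhhdyn.metrics import pb_frequencies, znormalise
        lo, hi = regions[3].core()
        core = range(lo - 1, hi)
        core_neq = [neq(pb_frequencies(pbm[:, i])) for i in core]
        assert min(core_neq) > 3.0
        z = znormalise(rmsf(ens).values)
        assert z[list(core)].max() <= 2.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FamilySpec(n_classes=1, domains_per_class=1, n_frames=5,
                       regions=[RegionSpec("a", 2, 5, ("rigid",))])
        with pytest.raises(ValueError):
            FamilySpec(n_classes=2, domains_per_class=1, n_frames=5,
                       regions=[RegionSpec("a", 1, 5, ("rigid",))])
        with pytest.raises(ValueError):
            FamilySpec(n_classes=1, domains_per_class=1, n_frames=5,
                       regions=[RegionSpec("a", 1, 5, ("rigid",))],
                       n_states=99)
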