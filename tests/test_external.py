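import numpy as np
import pytest

import clonalprof as cp
from clonalprof.external import ProfileSourceSpec, UnknownGermlineError
from clonalprof.profiles import AA_INDEX


def onehot_profile(aa, positions):
    return cp.SubstitutionProfile.one_hot(aa * len(positions), positions)


def tensor_of(profiles, ids=None):
    return cp.ProfileTensor.from_profiles(profiles, ids)


class TestSourceSpec:
    def test_names_round_trip(self):
        for name in ["vgene", "vsubgrp", "naiveAA", "neut",
                     "clust-7", "naiveAA-clust-85"]:
            assert ProfileSourceSpec.parse(name).name == name

    def test_cluster_k_bounds(self):
        with pytest.raises(ValueError):
            ProfileSourceSpec("clust", 1)
        with pytest.raises(ValueError):
            ProfileSourceSpec("clust", 121)
        with pytest.raises(ValueError):
            ProfileSourceSpec("vgene", 5)


class TestAverageByLabel:
    def test_two_onehots_average_to_half_half(self):
        pa = onehot_profile("A", [4])
        pc = onehot_profile("C", [4])
        public = tensor_of([pa, pc], ["a", "b"])
        out = cp.average_by_label(public, {"a": "V1", "b": "V1"})
        row = out["V1"].freqs[3]
        assert row[AA_INDEX["A"]] == pytest.approx(0.5)
        assert row[AA_INDEX["C"]] == pytest.approx(0.5)

    def test_single_member_is_fixed_point(self):
        pa = onehot_profile("W", [10, 11])
        public = tensor_of([pa, pa], ["a", "b"])
        out = cp.average_by_label(public, {"a": "V1", "b": "V2"})
        np.testing.assert_allclose(out["V1"].freqs, pa.freqs)
        np.testing.assert_allclose(out["V2"].freqs, pa.freqs)

    def test_undefined_members_excluded_from_positionwise_mean(self):
        pa = onehot_profile("A", [1, 2])
        pc = onehot_profile("C", [1])  # undefined at position 2
        public = tensor_of([pa, pc], ["a", "b"])
        out = cp.average_by_label(public, {"a": "V", "b": "V"})
        assert out["V"].freqs[1, AA_INDEX["A"]] == pytest.approx(1.0)
        assert out["V"].freqs[0, AA_INDEX["A"]] == pytest.approx(0.5)

    def test_missing_label_raises(self):
        public = tensor_of([onehot_profile("A", [1])], ["a"])
        with pytest.raises(KeyError):
            cp.average_by_label(public, {})


class TestNaiveProfile:
    def test_onehot_rows(self, toy_cf):
        prof = cp.naive_profile(toy_cf)
        prof.validate()
        assert prof.defined.sum() == len(toy_cf.numbering)
        for aa, j in zip(toy_cf.naive_aa, toy_cf.numbering):
            assert prof.freqs[j - 1, AA_INDEX[aa]] == 1.0


class TestKMeansProfiles:
    def _two_far_clusters(self):
        pa = onehot_profile("A", list(range(1, 21)))
        pw = onehot_profile("W", list(range(1, 21)))
        profiles = [pa, pa, pa, pw, pw, pw]
        return tensor_of(profiles, [f"c{i}" for i in range(6)]), pa, pw

    def test_duplicated_points_recovered_exactly(self):
        public, pa, pw = self._two_far_clusters()
        km = cp.kmeans_profiles(public, "frequency", k=2, seed=0)
        got = sorted(np.round(c.freqs[0], 6).argmax() for c in km.centroids)
        assert got == sorted([AA_INDEX["A"], AA_INDEX["W"]])
        # queries are assigned to the nearer duplicated profile
        assert km.profile_for(pa).freqs[0, AA_INDEX["A"]] == pytest.approx(1.0)
        assert km.profile_for(pw).freqs[0, AA_INDEX["W"]] == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self, small_dataset):
        pub = small_dataset.y
        a = cp.kmeans_profiles(pub, "frequency", k=3, seed=5)
        b = cp.kmeans_profiles(pub, "frequency", k=3, seed=5)
        np.testing.assert_array_equal(a.kmeans.labels_, b.kmeans.labels_)
        for ca, cb in zip(a.centroids, b.centroids):
            np.testing.assert_array_equal(ca.freqs, cb.freqs)

    def test_k1_centroid_is_elementwise_mean(self):
        public, *_ = self._two_far_clusters()
        km = cp.kmeans_profiles(public, "frequency", k=1, seed=0,
                                allow_small_k=True)
        mean = public.freqs.mean(axis=0)
        mean /= mean.sum(axis=1, keepdims=True).clip(1e-12)
        np.testing.assert_allclose(km.centroids[0].freqs[:20], mean[:20],
                                   atol=1e-9)

    def test_wcss_nonincreasing_in_k(self, small_dataset):
        pub = small_dataset.y
        inertias = [cp.kmeans_profiles(pub, "frequency", k=k, seed=0).kmeans.inertia_
                    for k in (2, 4, 8)]
        assert inertias[0] >= inertias[1] >= inertias[2]

    def test_k_exceeding_n_raises(self):
        public, *_ = self._two_far_clusters()
        with pytest.raises(ValueError):
            cp.kmeans_profiles(public, "frequency", k=7, seed=0)


class TestAssembleInputTensor:
    def test_naive_source_slab_matches_naive_profile(self, small_dataset):
        ds = small_dataset
        reg = cp.SourceRegistry()
        specs = (ProfileSourceSpec("naiveAA"),)
        xt = cp.assemble_input_tensor(ds.x, ds.cfs, specs, reg)
        for i, cf in enumerate(ds.cfs[:5]):
            expected = cp.naive_profile(cf).freqs
            np.testing.assert_allclose(xt.values[i, :, :, 0], expected)

    def test_index_convention_and_simplex_rows(self, small_dataset):
        ds = small_dataset
        reg = cp.SourceRegistry()
        xt = cp.assemble_input_tensor(ds.x, ds.cfs,
                                      (ProfileSourceSpec("naiveAA"),), reg)
        sums = xt.values.sum(axis=2)  # (n, 149, p)
        assert np.allclose(sums[xt.defined], 1.0, atol=1e-9)
        assert np.all(sums[~xt.defined] == 0.0)

    def test_p_zero_tensor(self, small_dataset):
        ds = small_dataset
        xt = cp.assemble_input_tensor(ds.x, ds.cfs, (), cp.SourceRegistry())
        assert xt.p == 0

    def test_unknown_v_gene_raises_with_cf_named(self, small_dataset):
        ds = small_dataset
        pub = tensor_of([onehot_profile("A", [1])], ["pub0"])
        reg = cp.SourceRegistry.from_public(pub, v_gene_labels={"pub0": "IGHVX"})
        with pytest.raises(UnknownGermlineError, match=ds.cfs[0].cf_id):
            cp.assemble_input_tensor(ds.x, ds.cfs,
                                     (ProfileSourceSpec("vgene"),), reg)

    def test_source_gap_falls_back_to_input_profile(self, small_dataset):
        ds = small_dataset
        # public average defined at a single position => fallback elsewhere
        pub = tensor_of([onehot_profile("A", [1])], ["pub0"])
        labels = {"pub0": ds.cfs[0].v_gene}
        reg = cp.SourceRegistry.from_public(pub, v_gene_labels=labels)
        cfs = [ds.cfs[0]]
        x1 = ds.x.subset([0])
        xt = cp.assemble_input_tensor(x1, cfs, (ProfileSourceSpec("vgene"),),
                                      reg)
        defined = x1.defined[0].copy()
        slab = xt.values[0, :, :, 0]
        assert slab[0, AA_INDEX["A"]] == pytest.approx(1.0)  # covered position
        defined[0] = False  # everywhere else the input profile is substituted
        np.testing.assert_allclose(slab[defined], x1.freqs[0][defined])
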