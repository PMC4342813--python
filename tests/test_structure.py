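"""AMOVA variance components, pairwise ΦST, and classical MDS."""

import numpy as np
import pytest

from mtlineage.codec import FRAME_CR, parse_haplotype
from mtlineage.diversity import PopulationSample
from mtlineage.structure import (
    DistanceMatrix,
    amova_two_level,
    classical_mds,
    pairwise_fst_matrix,
)
from tests.conftest import make_random_haplotype


def pop_of(texts, name="p"):
    return PopulationSample(
        name,
        [parse_haplotype(t, FRAME_CR, sample_id=f"{name}{i}") for i, t in enumerate(texts)],
        FRAME_CR,
    )


def fixed_difference_pair(k=3, n=4):
    tokens_a = " ".join(f"{100 + i}A" for i in range(k))
    return pop_of([tokens_a] * n, "a"), pop_of([""] * n, "b")


class TestAmova:
    def test_fixed_difference_populations(self):
        a, b = fixed_difference_pair(k=3, n=4)
        res = amova_two_level([a, b])
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)
        assert res.sigma2_within == 0.0

    def test_hand_computed_two_by_two(self):
        # A = {h0, h0}, B = {h1, h1}, d(h0,h1)=2: the 4 cross pairs sum to 8,
        # so SS_T = 8/4 = 2, SS_W = 0, MS_A = 2, n' = 2, sigma2_a = 1
        a = pop_of(["100A 101A"] * 2, "a")
        b = pop_of([""] * 2, "b")
        res = amova_two_level([a, b])
        assert res.ss_among == pytest.approx(2.0)
        assert res.ss_within == pytest.approx(0.0)
        assert res.sigma2_among == pytest.approx(1.0)

    def test_sum_of_squares_additivity_and_label_invariance(self, ref):
        rng = np.random.default_rng(10)
        pops = []
        for name, n in (("x", 5), ("y", 7), ("z", 4)):
            haps = [
                make_random_haplotype(rng, FRAME_CR, ref, sample_id=f"{name}{i}")
                for i in range(n)
            ]
            pops.append(PopulationSample(name, haps, FRAME_CR))
        res = amova_two_level(pops)
        # relabelling populations and shuffling their order is irrelevant
        res2 = amova_two_level(list(reversed(pops)))
        assert res2.phi_st == pytest.approx(res.phi_st)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)

    def test_null_pooled_populations_phi_near_zero(self, ref):
        rng = np.random.default_rng(55)
        pool = [make_random_haplotype(rng, FRAME_CR, ref, n_variants=(2, 8))
                for _ in range(40)]
        idx = rng.permutation(40)
        a = PopulationSample("a", [pool[i] for i in idx[:20]], FRAME_CR)
        b = PopulationSample("b", [pool[i] for i in idx[20:]], FRAME_CR)
        res = amova_two_level([a, b], n_permutations=200, seed=1)
        assert abs(res.phi_st) < 0.05
        assert res.p_value > 0.05

    def test_permutation_p_value_reproducible_and_bounded(self):
        a, b = fixed_difference_pair()
        r1 = amova_two_level([a, b], n_permutations=99, seed=7)
        r2 = amova_two_level([a, b], n_permutations=99, seed=7)
        assert r1.p_value == r2.p_value
        assert 1 / 100 <= r1.p_value <= 1.0

    def test_seed_mandatory_for_permutations(self):
        a, b = fixed_difference_pair()
        with pytest.raises(ValueError, match="seed"):
            amova_two_level([a, b], n_permutations=10)

    def test_small_population_rejected(self):
        a, _ = fixed_difference_pair()
        with pytest.raises(ValueError, match="n < 2"):
            amova_two_level([a, pop_of([""], "tiny")])


class TestPairwiseFst:
    def test_identical_and_fixed_extremes(self):
        a, b = fixed_difference_pair()
        same = pop_of(["73G", "73G", "150T", ""], "c")
        same2 = PopulationSample(
            "d", list(same.haplotypes), FRAME_CR
        )
        m = pairwise_fst_matrix([a, b, same, same2])
        labels = m.labels
        ab = m.d[labels.index("a"), labels.index("b")]
        cd = m.d[labels.index("c"), labels.index("d")]
        assert ab == pytest.approx(1.0)
        assert cd == 0.0  # floored; raw may be slightly negative
        assert m.raw[labels.index("c"), labels.index("d")] <= 0.0

    def test_matches_direct_two_population_amova(self, ref):
        rng = np.random.default_rng(3)
        pops = []
        for name in ("u", "v", "w"):
            haps = [make_random_haplotype(rng, FRAME_CR, ref) for _ in range(6)]
            pops.append(PopulationSample(name, haps, FRAME_CR))
        m = pairwise_fst_matrix(pops)
        for i in range(3):
            for j in range(i + 1, 3):
                direct = amova_two_level([pops[i], pops[j]]).phi_st
                assert m.raw[i, j] == pytest.approx(direct)


class TestClassicalMds:
    def test_right_triangle_distances_reproduced(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        res = classical_mds(D, k=2)
        emb = res.coordinates
        for i in range(3):
            for j in range(3):
                dij = np.linalg.norm(emb[i] - emb[j])
                assert dij == pytest.approx(D.d[i, j], abs=1e-9)

    def test_zero_matrix_embeds_at_origin(self):
        D = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        with pytest.warns(UserWarning):
            res = classical_mds(D, k=1)
        assert np.allclose(res.coordinates, 0.0)

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = classical_mds(DistanceMatrix([str(i) for i in range(8)], d), k=2)
        emb = res.coordinates
        rec = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        assert np.allclose(rec, d, atol=1e-9)
        # coordinates centred, eigenvalues descending
        assert np.allclose(emb.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_axis_sign_convention_deterministic(self):
        rng = np.random.default_rng(23)
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        D = DistanceMatrix(list("abcde"), d)
        c1 = classical_mds(D, k=2).coordinates
        c2 = classical_mds(D, k=2).coordinates
        assert np.array_equal(c1, c2)
        for axis in range(2):
            col = c1[:, axis]
            assert col[np.argmax(np.abs(col))] > 0

    def test_agrees_with_skbio_pcoa_up_to_sign(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(29)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ours = classical_mds(DistanceMatrix([str(i) for i in range(6)], d), k=3)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        ref_coords = theirs.samples.to_numpy()[:, :3]
        for axis in range(3):
            a, b = ours.coordinates[:, axis], ref_coords[:, axis]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_excess_dimensions_warn_and_shrink(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float))
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            res = classical_mds(D, k=3)
        assert res.coordinates.shape[1] < 3

    def test_distance_matrix_tsv_round_trip(self, tmp_path):
        d = np.array([[0, 1.5], [1.5, 0]])
        D = DistanceMatrix(["a", "b"], d)
        path = tmp_path / "d.tsv"
        D.write_tsv(path)
        back = DistanceMatrix.read_tsv(path)
        assert back.labels == ["a", "b"]
        assert np.allclose(back.d, d)
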