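"""Distance matrices, AMOVA/PhiST, pairwise PhiST and classical MDS."""

import itertools
import math

import numpy as np
import pytest

from mitostruct.differentiation import (
    DistanceMatrix,
    amova,
    classical_mds,
    difference_matrix,
    k2p_matrix,
    pairwise_fst,
)
from mitostruct.seq_io import Alignment

from conftest import random_alignment

MISSING = {"N", "-"}


def brute_force_differences(seqs):
    n = len(seqs)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = sum(
            1
            for a, b in zip(seqs[i], seqs[j])
            if a not in MISSING and b not in MISSING and a != b
        )
        out[i, j] = out[j, i] = d
    return out


def brute_force_amova(d, groups):
    """Variance decomposition by explicit double loops (independent of
    the vectorised implementation)."""
    N = d.shape[0]
    P = len(groups)
    ssd_total = sum(d[i, j] for i in range(N) for j in range(i + 1, N)) / N
    ssd_within = 0.0
    for members in groups:
        nk = len(members)
        ssd_within += (
            sum(
                d[a, b]
                for a, b in itertools.combinations(members, 2)
            )
            / nk
        )
    ssd_among = ssd_total - ssd_within
    s2_within = ssd_within / (N - P)
    n_prime = (N - sum(len(m) ** 2 for m in groups) / N) / (P - 1)
    s2_among = (ssd_among / (P - 1) - s2_within) / n_prime
    phi = s2_among / (s2_among + s2_within)
    return ssd_total, ssd_within, ssd_among, s2_among, s2_within, phi


class TestDifferenceMatrix:
    def test_identical_pair_zero(self):
        aln = Alignment(ids=("a", "b"), sequences=("ACGT", "ACGT"))
        assert difference_matrix(aln).values[0, 1] == 0

    def test_missing_site_dropped_pairwise(self):
        aln = Alignment(
            ids=("a", "b", "c"), sequences=("ACGT", "ACNT", "ACGT")
        )
        d = difference_matrix(aln).values
        assert d[0, 1] == 0 and d[1, 2] == 0 and d[0, 2] == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_recount(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=7, L=80, missing_rate=0.08)
        got = difference_matrix(aln).values
        np.testing.assert_array_equal(got, brute_force_differences(aln.sequences))

    def test_pair_without_joint_sites_raises_unless_allowed(self):
        aln = Alignment(ids=("a", "b"), sequences=("ANN", "NNG"))
        with pytest.raises(ValueError):
            difference_matrix(aln)
        d = difference_matrix(aln, allow_null=True).values
        assert np.isnan(d[0, 1])


class TestK2P:
    def test_identical_pair_zero(self):
        aln = Alignment(ids=("a", "b"), sequences=("ACGT" * 25, "ACGT" * 25))
        assert k2p_matrix(aln).values[0, 1] == 0.0

    def test_transition_only_formula(self):
        # 10 A<->G transitions over 100 sites: P=0.1, Q=0
        s1 = "A" * 100
        s2 = "G" * 10 + "A" * 90
        d = k2p_matrix(Alignment(ids=("a", "b"), sequences=(s1, s2))).values
        assert d[0, 1] == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    def test_transversion_only_formula(self):
        # 10 A<->C transversions over 100 sites: P=0, Q=0.1
        s1 = "A" * 100
        s2 = "C" * 10 + "A" * 90
        d = k2p_matrix(Alignment(ids=("a", "b"), sequences=(s1, s2))).values
        # -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q) with P=0, Q=0.1
        expected = -0.5 * math.log(0.9 * math.sqrt(0.8))
        assert d[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_saturation_yields_nan_with_warning(self):
        s1 = "A" * 10
        s2 = "G" * 10  # P=1.0 -> log argument <= 0
        with pytest.warns(UserWarning, match="saturated"):
            d = k2p_matrix(Alignment(ids=("a", "b"), sequences=(s1, s2))).values
        assert np.isnan(d[0, 1])


def _dist(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or tuple(f"s{i}" for i in range(values.shape[0]))
    return DistanceMatrix(ids=tuple(ids), values=values, metric="raw_differences")


class TestAmova:
    def test_fixed_distinct_haplotypes_give_phi_one(self):
        aln = Alignment(
            ids=tuple("abcd"),
            sequences=("AAAA", "AAAA", "TTTT", "TTTT"),
        )
        d = difference_matrix(aln)
        res = amova(d, {"g1": ("a", "b"), "g2": ("c", "d")}, n_perm=0)
        assert res.phi_st == pytest.approx(1.0)

    def test_three_group_decomposition_matches_manual_oracle(self, rng):
        aln = random_alignment(rng, n=6, L=60)
        d = difference_matrix(aln)
        partition = {
            "g1": ("s0", "s1"),
            "g2": ("s2", "s3"),
            "g3": ("s4", "s5"),
        }
        res = amova(d, partition, n_perm=0)
        exp = brute_force_amova(d.values, [(0, 1), (2, 3), (4, 5)])
        assert res.ssd_total == pytest.approx(exp[0], abs=1e-9)
        assert res.ssd_within == pytest.approx(exp[1], abs=1e-9)
        assert res.ssd_among == pytest.approx(exp[2], abs=1e-9)
        assert res.sigma2_among == pytest.approx(exp[3], abs=1e-9)
        assert res.sigma2_within == pytest.approx(exp[4], abs=1e-9)
        assert res.phi_st == pytest.approx(exp[5], abs=1e-9)

    def test_ssd_additivity(self, rng):
        aln = random_alignment(rng, n=9, L=120)
        d = difference_matrix(aln)
        partition = {
            "g1": ("s0", "s1", "s2"),
            "g2": ("s3", "s4", "s5"),
            "g3": ("s6", "s7", "s8"),
        }
        res = amova(d, partition, n_perm=0)
        assert res.ssd_among + res.ssd_within == pytest.approx(
            res.ssd_total, abs=1e-9
        )

    def test_permutation_p_reproducible_and_rename_invariant(self, rng):
        aln = random_alignment(rng, n=8, L=60)
        d = difference_matrix(aln)
        part = {"g1": tuple(f"s{i}" for i in range(4)),
                "g2": tuple(f"s{i}" for i in range(4, 8))}
        r1 = amova(d, part, n_perm=500, seed=42)
        r2 = amova(d, part, n_perm=500, seed=42)
        assert r1.p_value == r2.p_value
        renamed = {"zzz": part["g1"], "aaa": part["g2"]}
        r3 = amova(d, renamed, n_perm=500, seed=42)
        assert r3.p_value == r1.p_value
        assert r1.p_se == pytest.approx(
            math.sqrt(r1.p_value * (1 - r1.p_value) / 500)
        )

    def test_singleton_group_rejected(self, rng):
        aln = random_alignment(rng, n=3, L=20)
        d = difference_matrix(aln)
        with pytest.raises(ValueError):
            amova(d, {"g1": ("s0",), "g2": ("s1", "s2")}, n_perm=0)


class TestPairwiseFst:
    def test_diagonal_zero_and_symmetry(self, rng):
        aln = random_alignment(rng, n=9, L=60)
        d = difference_matrix(aln)
        part = {
            "g1": ("s0", "s1", "s2"),
            "g2": ("s3", "s4", "s5"),
            "g3": ("s6", "s7", "s8"),
        }
        fst = pairwise_fst(d, part)
        assert np.allclose(np.diag(fst.values), 0.0)
        assert np.allclose(fst.values, fst.values.T)

    def test_group_order_swap_transposes(self, rng):
        aln = random_alignment(rng, n=6, L=60)
        d = difference_matrix(aln)
        p1 = {"g1": ("s0", "s1"), "g2": ("s2", "s3"), "g3": ("s4", "s5")}
        p2 = {"g3": ("s4", "s5"), "g2": ("s2", "s3"), "g1": ("s0", "s1")}
        f1 = pairwise_fst(d, p1).to_frame()
        f2 = pairwise_fst(d, p2).to_frame()
        assert np.allclose(
            f1.loc[list(p1), list(p1)].to_numpy(),
            f2.loc[list(p1), list(p1)].to_numpy(),
        )

    def test_cell_matches_two_group_amova(self, rng):
        aln = random_alignment(rng, n=6, L=80)
        d = difference_matrix(aln)
        part = {"g1": ("s0", "s1", "s2"), "g2": ("s3", "s4", "s5")}
        fst = pairwise_fst(d, part)
        res = amova(d, part, n_perm=0)
        assert fst.values[0, 1] == pytest.approx(res.phi_st, abs=1e-12)


class TestClassicalMds:
    def test_recovers_planar_configuration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 2.0]])
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        coords = classical_mds(D, k=2).to_numpy()
        D_hat = np.linalg.norm(
            coords[:, None, :] - coords[None, :, :], axis=-1
        )
        np.testing.assert_allclose(D_hat, D, atol=1e-8)

    def test_two_points_on_first_axis(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        with pytest.warns(UserWarning):
            coords = classical_mds(D, k=2).to_numpy()
        assert coords.shape == (2, 1)
        assert sorted(coords[:, 0]) == pytest.approx([-1.5, 1.5])

    def test_interpoint_distances_match_eigen_oracle(self, rng):
        # PSD-compatible dissimilarity from random points in 3D
        pts = rng.normal(size=(6, 3))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        coords = classical_mds(D, k=3).to_numpy()
        # independent oracle: full eigendecomposition of the centred Gram
        J = np.eye(6) - np.ones((6, 6)) / 6
        B = -0.5 * J @ (D**2) @ J
        w, V = np.linalg.eigh(B)
        idx = np.argsort(w)[::-1][:3]
        expected = V[:, idx] * np.sqrt(np.maximum(w[idx], 0))
        D_hat = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        D_exp = np.linalg.norm(expected[:, None] - expected[None, :], axis=-1)
        np.testing.assert_allclose(D_hat, D_exp, atol=1e-8)

    def test_negative_entries_clamped(self):
        D = np.array([[0.0, -0.01, 0.5], [-0.01, 0.0, 0.4], [0.5, 0.4, 0.0]])
        coords = classical_mds(D, k=2)
        assert np.isfinite(coords.to_numpy()).all()
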