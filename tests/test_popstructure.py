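import warnings
from itertools import combinations

import numpy as np
import pytest

from adaptscan.genotype_io import MISSING
from adaptscan.popstructure import (
    PcaResult, allele_frequencies, kinship_king, pca, projection_distances,
)
from adaptscan.simdata import SimParams, simulate

from conftest import make_gm


class TestAlleleFrequencies:
    @pytest.mark.parametrize("dosages,expected", [
        ([0, 0, 0, 0], 0.0),
        ([2, 2], 1.0),
        ([0, 1, 2, MISSING], 0.5),  # 3 alt alleles / 6 observed
    ])
    def test_single_site(self, dosages, expected):
        gm = make_gm(np.array([dosages]).T)
        assert allele_frequencies(gm)[0] == pytest.approx(expected)

    def test_per_group(self):
        gm = make_gm(
            np.array([[0, 0, 2, 2]]).T, populations=["a", "a", "b", "b"]
        )
        freqs = allele_frequencies(gm, by=True)
        assert freqs["a"][0] == 0.0
        assert freqs["b"][0] == 1.0

    def test_absent_group_errors(self):
        gm = make_gm(np.array([[0, 1]]).T, populations=["a", "a"])
        with pytest.raises(KeyError):
            gm.samples.group_indices("zzz")


class TestPca:
    def test_identical_samples_coincide(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(5, 40)).astype(np.int16)
        dosage = np.vstack([base, base[2:3]])  # sample 5 duplicates sample 2
        res = pca(make_gm(dosage), scaling_mode="center_only")
        np.testing.assert_allclose(
            res.projections[2], res.projections[5], atol=1e-9
        )

    def test_variance_explained_ordered_and_bounded(self):
        rng = np.random.default_rng(1)
        gm = make_gm(rng.integers(0, 3, size=(8, 60)).astype(np.int16))
        for mode in ("patterson", "center_only"):
            res = pca(gm, scaling_mode=mode)
            ve = res.variance_explained
            assert (ve >= 0).all()
            assert (np.diff(ve) <= 1e-9).all()
            assert ve.sum() <= 100.0 + 1e-9

    def test_two_block_toy_matches_eigen_oracle(self):
        # two 3-sample blocks of strongly divergent genotypes
        rng = np.random.default_rng(2)
        block1 = rng.integers(0, 2, size=(3, 50))
        block2 = block1[::-1] * 0 + 2 - rng.integers(0, 2, size=(3, 50))
        dosage = np.vstack([block1, block2]).astype(np.int16)
        gm = make_gm(dosage)
        res = pca(gm, scaling_mode="center_only")

        # PC1 separates the blocks with opposite signs
        pc1 = res.pc1
        assert np.sign(pc1[:3]).min() == np.sign(pc1[:3]).max()
        assert np.sign(pc1[3:]).min() == np.sign(pc1[3:]).max()
        assert np.sign(pc1[0]) == -np.sign(pc1[3])

        # eigenvalues from a brute-force decomposition of the centered
        # sample covariance (independent of the SVD route)
        x = dosage - dosage.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(x @ x.T))[::-1]
        eig = eig[eig > 1e-8]
        svd_eig = (res.projections**2).sum(axis=0)
        np.testing.assert_allclose(svd_eig, eig[: len(svd_eig)], atol=1e-8)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(7, 50)).astype(np.int16)
        perm = rng.permutation(7)
        r1 = pca(make_gm(dosage))
        r2 = pca(make_gm(dosage[perm]))
        # same axes up to sign; compare absolute projections
        np.testing.assert_allclose(
            np.abs(r1.projections[perm]), np.abs(r2.projections), atol=1e-8
        )
        np.testing.assert_allclose(
            r1.variance_explained, r2.variance_explained, atol=1e-8
        )

    def test_mean_imputed_cells_contribute_zero_difference(self):
        # projections preserve row distances of the centered matrix, and
        # an imputed cell sits exactly at the site mean, so the missing
        # cell adds nothing to any pairwise distance
        dosage = np.array(
            [[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, MISSING]], dtype=np.int16
        )
        res = pca(make_gm(dosage), scaling_mode="center_only")
        d02 = np.linalg.norm(res.projections[0] - res.projections[2])
        # hand-centered distance over the three fully observed sites only
        obs = dosage[:, :3].astype(float)
        xc = obs - obs.mean(axis=0)
        assert d02 == pytest.approx(np.linalg.norm(xc[0] - xc[2]), abs=1e-9)

    def test_all_missing_site_rejected(self):
        dosage = np.array([[0, 1], [MISSING, MISSING], [1, 2]]).T
        with pytest.raises(ValueError, match="apply_filters"):
            pca(make_gm(dosage))


class TestProjectionDistances:
    def test_three_four_five(self):
        res = PcaResult(
            np.array([[0.0, 0.0], [3.0, 4.0]]), np.array([60.0, 40.0]),
            "center_only", ["a", "b"],
        )
        df = projection_distances(res, ["g", "g"])
        assert df.loc[0, "mean_distance"] == pytest.approx(5.0)
        assert df.loc[0, "sd_distance"] == pytest.approx(0.0)

    def test_degenerate_identical_projections(self):
        res = PcaResult(
            np.zeros((4, 2)), np.array([50.0, 50.0]), "center_only",
            list("abcd"),
        )
        df = projection_distances(res, ["g"] * 4)
        assert df.loc[0, "mean_distance"] == 0.0
        assert df.loc[0, "sd_distance"] == 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 3))
        res = PcaResult(
            pts, np.array([50.0, 30.0, 20.0]), "center_only", list("abcde")
        )
        df = projection_distances(res, ["g"] * 5)
        dists = [
            np.linalg.norm(pts[i] - pts[j])
            for i, j in combinations(range(5), 2)
        ]
        assert df.loc[0, "mean_distance"] == pytest.approx(np.mean(dists))
        assert df.loc[0, "sd_distance"] == pytest.approx(np.std(dists))
        assert df.loc[0, "n_pairs"] == 10

    def test_singleton_group_warns_nan(self):
        res = PcaResult(
            np.zeros((3, 1)), np.array([100.0]), "center_only", list("abc")
        )
        with pytest.warns(UserWarning, match="single sample"):
            df = projection_distances(res, ["g", "g", "solo"])
        assert np.isnan(df.set_index("population").loc["solo",
                                                       "mean_distance"])


class TestKinshipKing:
    def test_duplicate_sample_is_half(self):
        rng = np.random.default_rng(5)
        row = rng.integers(0, 3, size=100).astype(np.int16)
        assert (row == 1).sum() > 0
        gm = make_gm(np.vstack([row, row]))
        kin = kinship_king(gm)
        assert kin.values[0, 1] == 0.5

    def test_hand_counted_toy_pair(self):
        # i=[1,1,0,2,1], j=[1,0,2,2,1]: N_hethet=2 (sites 1,5),
        # N_opp=1 (site 3), N_het(i)=3, N_het(j)=2 -> (2-2)/5 = 0
        gm = make_gm(np.array([[1, 1, 0, 2, 1], [1, 0, 2, 2, 1]],
                              dtype=np.int16))
        kin = kinship_king(gm)
        assert kin.values[0, 1] == pytest.approx(0.0)

    def test_diagonal_convention_and_symmetry(self):
        rng = np.random.default_rng(6)
        gm = make_gm(rng.integers(0, 3, size=(5, 200)).astype(np.int16))
        kin = kinship_king(gm)
        np.testing.assert_array_equal(np.diag(kin.values), 0.5)
        np.testing.assert_allclose(kin.values, kin.values.T)

    def test_parent_offspring_near_quarter(self):
        # Mendelian oracle: offspring inherits one allele from the parent,
        # the other from the population
        rng = np.random.default_rng(7)
        L, n_pairs = 5000, 10
        p = rng.uniform(0.1, 0.9, size=L)
        rows = []
        for _ in range(n_pairs):
            parent = rng.binomial(1, p, size=(2, L))
            transmitted = np.take_along_axis(
                parent, rng.integers(0, 2, size=(1, L)), axis=0
            )[0]
            other = rng.binomial(1, p)
            rows.append(parent.sum(axis=0))
            rows.append(transmitted + other)
        gm = make_gm(np.array(rows, dtype=np.int16))
        kin = kinship_king(gm)
        po = [kin.values[2 * k, 2 * k + 1] for k in range(n_pairs)]
        assert np.mean(po) == pytest.approx(0.25, abs=0.03)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(8)
        dosage = rng.integers(0, 3, size=(6, 300)).astype(np.int16)
        dosage[rng.random(size=dosage.shape) < 0.05] = MISSING
        flip = rng.random(300) < 0.5
        flipped = dosage.copy()
        sub = flipped[:, flip]
        sub[sub != MISSING] = 2 - sub[sub != MISSING]
        flipped[:, flip] = sub
        k1 = kinship_king(make_gm(dosage))
        k2 = kinship_king(make_gm(flipped))
        np.testing.assert_allclose(k1.values, k2.values, atol=1e-12)

    def test_no_het_pair_warns_nan(self):
        gm = make_gm(np.array([[0, 0, 2], [2, 0, 0]], dtype=np.int16))
        with pytest.warns(UserWarning, match="no heterozygous"):
            kin = kinship_king(gm)
        assert np.isnan(kin.values[0, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_between_population_kinship_below_within(self, seed):
        gm, _ = simulate(SimParams(
            seed=seed, n_sites=1500, fst_param=0.05, n_adaptive=0,
            admix_fraction=0.0, missing_rate=0.0,
        ))
        kin = kinship_king(gm).values
        pop = np.array(gm.samples.population)
        within, between = [], []
        n = len(pop)
        for i in range(n):
            for j in range(i + 1, n):
                (within if pop[i] == pop[j] else between).append(
                    kin[i, j]
                )
        assert np.nanmean(between) < np.nanmean(within)
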