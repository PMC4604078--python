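"""geNorm, 2^-ddCt, z-scoring and Ward clustering against oracles."""

import numpy as np
import pandas as pd
import pytest

from dystromorph import expression as ex, synth


def _ct(mat, genes, samples=None):
    samples = samples or [f"s{i + 1}" for i in range(np.shape(mat)[1])]
    return pd.DataFrame(np.asarray(mat, float), index=genes, columns=samples)


class TestGeNorm:
    def test_identical_table_all_zero_m(self):
        ct = _ct(np.tile([[20.0, 21.0, 22.0]], (4, 1)), list("abcd"))
        m = ex.genorm_m(ct)
        assert np.allclose(m.values, 0.0, atol=1e-12)

    def test_constant_offset_pair_has_zero_pairwise_sd(self):
        # two genes differing by a constant Ct across samples contribute
        # nothing to each other's M
        base = np.array([20.0, 22.0, 19.0, 23.0])
        ct = _ct([base, base + 3.0, base + np.array([0, 1, -1, 0.5])],
                 ["a", "b", "noisy"])
        m = ex.genorm_m(ct)
        # a and b see each other at SD 0, both only penalized by 'noisy'
        assert m["a"] == pytest.approx(m["b"])
        assert m["noisy"] > m["a"]

    def test_planted_unstable_gene_excluded_first(self):
        ct, truth = synth.generate_ct_table(
            8, ["r1", "r2", "r3", "bad"], stable_refs=3, noise_sd=1.5, seed=5)
        rank = ex.genorm_stability(ct)
        first_out = rank[rank.exclusion_order == 1].index[0]
        assert first_out == "bad"

    def test_offset_invariance(self):
        ct, _ = synth.generate_ct_table(6, list("abcde"), 2, noise_sd=1.0, seed=3)
        shifted = ct.add(pd.Series({g: i * 2.0 for i, g in enumerate(ct.index)}),
                        axis=0)
        pd.testing.assert_series_equal(ex.genorm_m(ct), ex.genorm_m(shifted))

    def test_too_few_candidates_rejected(self):
        ct = _ct([[20, 21], [20, 21]], ["a", "b"])
        with pytest.raises(ex.ExpressionError):
            ex.genorm_stability(ct)


class TestDdct:
    GROUPS = pd.Series({"s1": "ctl", "s2": "ctl", "s3": "trt", "s4": "trt"})

    def test_no_change_gives_fold_one(self):
        ct = _ct([[20, 20, 20, 20], [25, 25, 25, 25]], ["ref", "tgt"])
        res = ex.ddct(ct, ["ref"], self.GROUPS, "ctl")
        assert np.allclose(res.fold_change, 1.0)

    def test_one_cycle_drop_doubles_expression(self):
        ct = _ct([[20, 20, 20, 20], [25, 25, 24, 24]], ["ref", "tgt"])
        res = ex.ddct(ct, ["ref"], self.GROUPS, "ctl")
        trt = res[(res.gene == "tgt") & (res.group == "trt")].fold_change.iloc[0]
        assert trt == pytest.approx(2.0)

    def test_random_table_vs_spreadsheet_oracle(self, rng):
        genes = ["ref1", "ref2", "tgt"]
        ct = _ct(rng.uniform(18, 30, (3, 4)), genes)
        res = ex.ddct(ct, ["ref1", "ref2"], self.GROUPS, "ctl")
        # independent cell-by-cell arithmetic
        dct = ct.loc["tgt"] - (ct.loc["ref1"] + ct.loc["ref2"]) / 2
        ddct_trt = (dct[["s3", "s4"]].mean() - dct[["s1", "s2"]].mean())
        want = 2.0 ** -ddct_trt
        got = res[(res.gene == "tgt") & (res.group == "trt")].fold_change.iloc[0]
        assert got == pytest.approx(want, abs=1e-9)

    def test_per_sample_constant_shift_equivariance(self, rng):
        genes = ["ref1", "ref2", "tgt"]
        ct = _ct(rng.uniform(18, 30, (3, 4)), genes)
        shifted = ct.copy()
        shifted["s3"] += 1.7     # loading offset hits every gene of one sample
        a = ex.ddct(ct, ["ref1", "ref2"], self.GROUPS, "ctl")
        b = ex.ddct(shifted, ["ref1", "ref2"], self.GROUPS, "ctl")
        # the references absorb the shift, so dCt and the folds are unchanged
        pd.testing.assert_frame_equal(a, b)

    def test_missing_calibrator_rejected(self):
        ct = _ct([[20, 20, 20, 20], [25, 25, 25, 25]], ["ref", "tgt"])
        with pytest.raises(ex.ExpressionError):
            ex.ddct(ct, ["ref"], self.GROUPS, "nope")


class TestZscore:
    def test_constant_row_removed(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [10.0, 100.0, 5.0]],
                          index=["flat", "ok"])
        z = ex.zscore_log(df)
        assert list(z.index) == ["ok"]

    def test_two_point_row(self):
        df = pd.DataFrame([[10.0, 100.0]], index=["g"])
        z = ex.zscore_log(df)
        assert z.loc["g"].tolist() == pytest.approx([-0.7071067811865476,
                                                     0.7071067811865476])

    def test_rows_standardized(self):
        fpkm, _ = synth.generate_fpkm_matrix(50, 8, seed=2)
        z = ex.zscore_log(fpkm)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_rows_with_missing_values_removed(self):
        df = pd.DataFrame([[1.0, np.nan, 3.0], [1.0, 2.0, 3.0]],
                          index=["drop", "keep"])
        assert list(ex.zscore_log(df).index) == ["keep"]

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ex.ExpressionError):
            ex.zscore_log(pd.DataFrame([[-1.0, 2.0]]))


def _ward_oracle(mat):
    """O(n^3) Ward.D2 agglomeration via the Lance-Williams update."""
    n = mat.shape[0]
    d2 = ((mat[:, None, :] - mat[None, :, :]) ** 2).sum(-1)   # squared dists
    active = {i: (1, i) for i in range(n)}   # id -> (size, label)
    merges = []
    next_id = n
    d2 = d2.astype(float)
    ids = list(range(n))
    dist = {frozenset((i, j)): d2[i, j] for i in ids for j in ids if i < j}
    sizes = {i: 1 for i in ids}
    while len(ids) > 1:
        pair = min((p for p in dist if p.issubset(ids)), key=lambda p: dist[p])
        i, j = sorted(pair)
        h = np.sqrt(dist[pair])
        merges.append((i, j, h))
        k = next_id
        next_id += 1
        sizes[k] = sizes[i] + sizes[j]
        for m in ids:
            if m in (i, j):
                continue
            dik = dist[frozenset((i, m))]
            djk = dist[frozenset((j, m))]
            dij = dist[pair]
            si, sj, sm = sizes[i], sizes[j], sizes[m]
            new = ((si + sm) * dik + (sj + sm) * djk - sm * dij) / (si + sj + sm)
            dist[frozenset((k, m))] = new
        ids = [m for m in ids if m not in (i, j)] + [k]
    return merges


class TestWard:
    def test_identical_rows_merge_first_at_zero(self):
        z = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, -1.0]],
                         index=list("abc"))
        cl = ex.ward_cluster(z)
        lk = cl["linkage"]
        assert lk[0, 2] == pytest.approx(0.0)
        assert {int(lk[0, 0]), int(lk[0, 1])} == {0, 1}

    def test_merge_heights_non_decreasing(self):
        fpkm, _ = synth.generate_fpkm_matrix(30, 8, seed=6)
        lk = ex.ward_cluster(ex.zscore_log(fpkm))["linkage"]
        assert (np.diff(lk[:, 2]) >= -1e-12).all()

    def test_planted_two_cluster_split_recovered(self):
        fpkm, labels = synth.generate_fpkm_matrix(60, 10, seed=7)
        z = ex.zscore_log(fpkm)
        rec = ex.cut_two(ex.ward_cluster(z, axis="columns"))
        agree = max((rec == labels).mean(), (rec != labels).mean())
        assert agree == 1.0

    def test_matches_brute_force_oracle_n12(self, rng):
        mat = rng.normal(0, 1, (12, 5))
        lk = ex.ward_cluster(pd.DataFrame(mat))["linkage"]
        oracle = _ward_oracle(mat)
        for row, (i, j, h) in zip(lk, oracle):
            assert {int(row[0]), int(row[1])} == {i, j}
            assert row[2] == pytest.approx(h, rel=1e-9)

    def test_row_order_invariance_of_heights(self, rng):
        mat = rng.normal(0, 1, (10, 4))
        df = pd.DataFrame(mat, index=[f"g{i}" for i in range(10)])
        perm = rng.permutation(10)
        lk1 = ex.ward_cluster(df)["linkage"]
        lk2 = ex.ward_cluster(df.iloc[perm])["linkage"]
        assert np.allclose(np.sort(lk1[:, 2]), np.sort(lk2[:, 2]))

    def test_newick_roundtrip_parses(self):
        z = pd.DataFrame([[1.0, 2.0], [1.5, 2.5], [5.0, -1.0]],
                         index=list("abc"))
        nwk = ex.to_newick(ex.ward_cluster(z))
        assert nwk.endswith(";") and nwk.count("(") == 2
        for leaf in "abc":
            assert leaf in nwk
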