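"""Differential-accessibility statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, nbinom, binom

from regcircuit import diffacc, synthetic
from regcircuit.diffacc import (
    CountMatrix,
    cpm_filter,
    da_table,
    estimate_dispersion,
    mds_embedding,
    nb_exact_test,
    scale_to_common_libsize,
    timepoint_specific_peaks,
    tmm_factors,
)


def make_matrix(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{j+1}" for j in range(arr.shape[1])]
    return CountMatrix(
        pd.DataFrame(arr, index=[f"f{i+1}" for i in range(arr.shape[0])], columns=samples)
    )


class TestCpmFilter:
    def test_rule_on_forced_examples(self):
        # library sizes equalised by a dominant row; row f1 has 1 CPM only
        # in two of four samples so the n-1 rule drops it
        base = np.full((1, 4), 10**6 - 5)
        m = make_matrix(np.vstack([[0, 0, 2, 3], base]))
        kept = cpm_filter(m)
        assert list(kept.features) == ["f2"]

    def test_all_zero_row_dropped(self):
        m = make_matrix([[0, 0, 0], [5, 5, 5]])
        assert list(cpm_filter(m, min_samples=2).features) == ["f2"]

    def test_empty_result_warns(self):
        m = make_matrix([[1, 1, 1]])
        with pytest.warns(UserWarning, match="every feature"):
            cpm_filter(m, min_cpm=1e9)

    def test_matches_direct_rule_evaluation(self):
        rng = np.random.default_rng(0)
        counts = rng.negative_binomial(2, 0.02, size=(1000, 5))
        m = make_matrix(counts)
        kept = set(cpm_filter(m).features)
        lib = counts.sum(axis=0)
        expected = {
            f"f{i+1}"
            for i in range(1000)
            if (counts[i] / lib * 1e6 >= 1.0).sum() >= 4
        }
        assert kept == expected


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        m = make_matrix(np.tile([[10], [60], [200]], (1, 2)))
        assert np.allclose(tmm_factors(m), 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(5, 500, 400)
        m = make_matrix(np.column_stack([col, 2 * col]))
        assert np.allclose(tmm_factors(m), 1.0)

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(4, 0.02, size=(2000, 3)) + 1
        # inflate the top 5% of one sample to create a composition bias
        order = np.argsort(counts[:, 2])
        counts[order[-100:], 2] *= 10
        m = make_matrix(counts)
        got = tmm_factors(m).to_numpy()
        expected = _tmm_oracle(counts.astype(float))
        assert np.allclose(got, expected, atol=1e-6)


def _tmm_oracle(counts):
    """Straight-line restatement of the TMM rule, written independently."""
    lib = counts.sum(axis=0)
    q = [np.sort(counts[:, j] / lib[j])[int(np.ceil(0.75 * len(counts))) - 1] for j in range(counts.shape[1])]
    q = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(q - q.mean())))
    logf = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        ok = (counts[:, j] > 0) & (counts[:, ref] > 0)
        o, r = counts[ok, j], counts[ok, ref]
        M = np.log2((o / lib[j]) / (r / lib[ref]))
        A = 0.5 * np.log2((o / lib[j]) * (r / lib[ref]))
        v = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        n = len(M)
        rm = pd.Series(M).rank().to_numpy()
        ra = pd.Series(A).rank().to_numpy()
        keep = (
            (rm >= np.floor(0.3 * n) + 1)
            & (rm <= n - np.floor(0.3 * n))
            & (ra >= np.floor(0.05 * n) + 1)
            & (ra <= n - np.floor(0.05 * n))
        )
        logf[j] = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    f = 2.0 ** logf
    return f / np.exp(np.mean(np.log(f)))


class TestDispersion:
    def test_parameter_recovery(self):
        m, _, _ = synthetic.simulate_contrast_counts(2000, seed=11)
        groups = ["g1"] * 3 + ["g2"] * 3
        est = estimate_dispersion(scale_to_common_libsize(m), groups)
        assert 0.08 <= est.phi <= 0.12

    def test_poisson_boundary(self):
        m, _, _ = synthetic.simulate_contrast_counts(2000, dispersion=0.0, seed=12)
        est = estimate_dispersion(scale_to_common_libsize(m), ["g1"] * 3 + ["g2"] * 3)
        assert est.phi <= 0.01

    def test_degenerate_data_warns_and_returns_grid_minimum(self):
        m = make_matrix([[7, 7, 7, 7]])
        with pytest.warns(UserWarning, match="no dispersion information"):
            est = estimate_dispersion(m, ["g1", "g1", "g2", "g2"])
        assert est.phi == pytest.approx(1e-4)

    def test_no_replication_raises(self):
        m = make_matrix([[5, 9]])
        with pytest.raises(ValueError, match="replication"):
            estimate_dispersion(m, ["g1", "g2"])


class TestExactTest:
    def test_symmetric_split_gives_p_one(self):
        assert nb_exact_test([3, 3], [3, 3], 0.1) == pytest.approx(1.0)

    def test_zero_total_gives_p_one(self):
        assert nb_exact_test([0, 0], [0, 0], 0.5) == 1.0

    def test_matches_conditional_enumeration(self):
        # oracle: condition two NB group sums (scipy pmfs at an arbitrary
        # mean) on their total and apply the small-p rule
        def oracle(sa, sb, na, nb, phi, mean=7.3):
            t = sa + sb
            k = np.arange(t + 1)
            if phi == 0:
                f = binom.pmf(k, t, na / (na + nb))
            else:
                ra, rb = na / phi, nb / phi
                f = nbinom.pmf(k, ra, ra / (ra + na * mean)) * nbinom.pmf(
                    t - k, rb, rb / (rb + nb * mean)
                )
            f = f / f.sum()
            return f[f <= f[sa] * (1 + 1e-7)].sum()

        for phi in (0.0, 0.1, 1.0):
            for na, nb in ((1, 1), (3, 3), (2, 3)):
                for t in range(1, 31):
                    for sa in range(t + 1):
                        a = [sa] + [0] * (na - 1)
                        b = [t - sa] + [0] * (nb - 1)
                        got = nb_exact_test(a, b, phi)
                        assert got == pytest.approx(oracle(sa, t - sa, na, nb, phi), abs=1e-10)

    def test_poisson_limit_matches_exact_binomial(self):
        for na, nb in ((3, 3), (2, 3)):
            for sa, sb in ((5, 0), (12, 3), (0, 9), (7, 7)):
                got = nb_exact_test([sa] + [0] * (na - 1), [sb] + [0] * (nb - 1), 0.0)
                want = binomtest(sa, sa + sb, na / (na + nb)).pvalue
                assert got == pytest.approx(want, abs=1e-10)


class TestDATable:
    def test_group_swap_negates_log2fc(self):
        m, sheet, _ = synthetic.simulate_contrast_counts(300, da_fraction=0.2, seed=21)
        fwd = da_table(m, sheet, ("g1", "g2"))
        rev = da_table(m, sheet, ("g2", "g1"))
        merged = fwd.merge(rev, on="feature", suffixes=("_f", "_r"))
        assert np.allclose(merged["log2fc_f"], -merged["log2fc_r"], atol=1e-6)
        assert np.allclose(merged["p_value_f"], merged["p_value_r"], atol=1e-9)

    def test_bh_fdr_properties(self):
        m, sheet, _ = synthetic.simulate_contrast_counts(500, seed=22)
        da = da_table(m, sheet, ("g1", "g2"))
        assert (da["fdr"] >= da["p_value"] - 1e-12).all()
        # monotone: sorting by p, adjusted values are non-decreasing
        s = da.sort_values("p_value")
        assert (np.diff(s["fdr"]) >= -1e-12).all()

    def test_missing_group_raises(self):
        m, sheet, _ = synthetic.simulate_contrast_counts(10, seed=1)
        with pytest.raises(ValueError, match="without samples"):
            da_table(m, sheet, ("g1", "nope"))

    def test_direction_is_ns_iff_above_alpha(self):
        m, sheet, _ = synthetic.simulate_contrast_counts(500, da_fraction=0.3, seed=23)
        da = da_table(m, sheet, ("g1", "g2"), alpha=0.05)
        assert ((da["direction"] == "ns") == (da["fdr"] > 0.05)).all()


class TestTimepointSpecific:
    @staticmethod
    def fake_da(features, direction, contrast):
        df = pd.DataFrame({"feature": features, "direction": direction})
        df.attrs["contrast"] = contrast
        return df

    def test_transient_peak(self):
        prev = self.fake_da(["p1"], ["up_in_2"], ("a", "t"))
        nxt = self.fake_da(["p1"], ["up_in_1"], ("t", "b"))
        u1, tr, u2 = timepoint_specific_peaks(prev, nxt)
        assert (u1, tr, u2) == (set(), {"p1"}, set())

    def test_empty_tables(self):
        prev = self.fake_da([], [], ("a", "t"))
        nxt = self.fake_da([], [], ("t", "b"))
        assert timepoint_specific_peaks(prev, nxt) == (set(), set(), set())

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(31)
        feats = [f"p{i}" for i in range(1000)]
        d1 = rng.choice(["up_in_2", "up_in_1", "ns"], 1000)
        d2 = rng.choice(["up_in_2", "up_in_1", "ns"], 1000)
        prev = self.fake_da(feats, d1, ("a", "t"))
        nxt = self.fake_da(feats, d2, ("t", "b"))
        u1, tr, u2 = timepoint_specific_peaks(prev, nxt)
        sp = {f for f, d in zip(feats, d1) if d == "up_in_2"}
        sn = {f for f, d in zip(feats, d2) if d == "up_in_1"}
        assert (u1, tr, u2) == (sp - sn, sp & sn, sn - sp)


class TestMDS:
    def test_duplicated_groups_collapse(self):
        rng = np.random.default_rng(41)
        a = rng.integers(10, 1000, 300)
        b = rng.integers(10, 1000, 300)
        m = make_matrix(np.column_stack([a, a, b, b]))
        xy = mds_embedding(m).to_numpy()
        assert np.linalg.norm(xy[0] - xy[1]) < 1e-8
        assert np.linalg.norm(xy[2] - xy[3]) < 1e-8
        assert np.linalg.norm(xy[0] - xy[2]) > 1e-3

    def test_three_samples_reproduce_distances_exactly(self):
        rng = np.random.default_rng(42)
        m = make_matrix(rng.integers(10, 2000, size=(400, 3)))
        lc = diffacc.cpm(m, log2=True).to_numpy()
        var = lc.var(axis=1)
        top = lc[np.argsort(-var, kind="stable")[:400]].T
        want = np.sqrt(((top[:, None] - top[None, :]) ** 2).sum(-1))
        xy = mds_embedding(m, top_n=400).to_numpy()
        got = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
        assert np.allclose(got, want, atol=1e-8)

    def test_sample_order_invariance_up_to_procrustes(self):
        rng = np.random.default_rng(43)
        counts = rng.integers(10, 2000, size=(300, 5))
        m = make_matrix(counts)
        perm = [3, 1, 4, 0, 2]
        m2 = make_matrix(counts[:, perm], samples=[f"s{j+1}" for j in perm])
        a = mds_embedding(m).loc[[f"s{j+1}" for j in perm]].to_numpy()
        b = mds_embedding(m2).to_numpy()
        # optimal orthogonal alignment (Procrustes) residual ~ 0
        u, _, vt = np.linalg.svd(b.T @ a)
        resid = np.linalg.norm(b @ (u @ vt) - a)
        assert resid < 1e-6
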