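"""Normalization, the exact count test, replicate summaries, clustering.

The worked examples pin the arithmetic to the published values of the study
this pipeline reproduces: per-million normalization with a 0.01
pseudo-count, log2 fold changes, exact-test tails, and the mean +/- SEM
replicate summaries.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom

import srnapipe as sp
from srnapipe.diffexpr import DEConfig, _log_pmf, cluster_expression

N_CON1, N_TEST1, N_TEST2 = 6_353_410, 4_421_513, 5_146_805


class TestNormalize:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (10, N_CON1, 1.574),
            (21, N_TEST1, 4.7495),
            (2, N_CON1, 0.3148),
            (11, N_TEST1, 2.4878),
            (159024, N_CON1, 25029.7),
            (41106, N_TEST2, 7986.702),
            (308, N_CON1, 48.4777),
            (115, N_TEST2, 22.344),
            (8, N_TEST2, 1.5544),
            (3, N_TEST2, 0.5829),
            (114725, N_TEST1, 25947.0),
        ],
    )
    def test_published_values(self, count, total, expected):
        assert sp.normalize(count, total) == pytest.approx(expected, rel=5e-4)

    def test_zero_count_pseudo(self):
        assert sp.normalize(0, 12345) == 0.01

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            sp.normalize(-1, 100)
        with pytest.raises(ValueError):
            sp.normalize(1, 0)

    def test_monotone_in_count(self):
        vals = [sp.normalize(c, 1000) for c in range(0, 30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected,tol",
        [
            (1.574, 4.7495, 1.59334, 1e-4),
            (0.3148, 2.4878, 2.982363, 5e-4),
            (25029.7, 7986.702, -1.64797, 5e-4),
            (48.4777, 22.344, -1.11744, 5e-4),
            (4.7495, 1.5544, -1.61142, 5e-4),
            (2.4878, 0.5829, -2.09355, 5e-4),
            (25947.0, 7986.702, -1.6999, 5e-4),
        ],
    )
    def test_published_values(self, a, b, expected, tol):
        assert sp.fold_change(a, b) == pytest.approx(expected, abs=tol)

    def test_identity_and_antisymmetry(self):
        assert sp.fold_change(3.7, 3.7) == 0.0
        assert sp.fold_change(1.5, 6.0) == -sp.fold_change(6.0, 1.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sp.fold_change(0.0, 1.0)


class TestExactTest:
    def test_closed_form_geometric_tail(self):
        """x=0 with equal library sizes: p(y|0) = 2^-(y+1), so the upper tail
        at y=5 is exactly 2^-5."""
        _pl, pu, _pr = sp.exact_count_pvalue(0, 5, 1000, 1000)
        assert pu == pytest.approx(2**-5, abs=1e-12)

    @staticmethod
    def _pmf(x, y, n1, n2):
        r = n2 / n1
        return float(np.exp(_log_pmf(np.array([y]), x, math.log(r), math.log1p(r)))[0])

    def test_tails_overlap_at_observed_point(self):
        for x, y, n1, n2 in [(7, 7, 500, 500), (12, 30, 1000, 1700)]:
            pl, pu, _ = sp.exact_count_pvalue(x, y, n1, n2)
            assert pl + pu == pytest.approx(1 + self._pmf(x, y, n1, n2), abs=1e-9)

    def test_symmetric_case_capped_at_one(self):
        _pl, _pu, pr = sp.exact_count_pvalue(9, 9, 800, 800, sided="two")
        assert pr == 1.0

    def test_symmetry_under_library_swap(self):
        """Swapping the roles of the two libraries maps the strict upper
        tail onto the inclusive lower tail: P(Y > y | x; N1,N2) =
        P(X' <= x | y; N2,N1). With inclusive tails on both sides the
        identity carries the observed-point pmf."""
        for x, y, n1, n2 in [(3, 11, 900, 900), (0, 4, 500, 500), (25, 25, 700, 700),
                             (40, 8, 1000, 1000), (12, 30, 1000, 1700)]:
            _, pu, _ = sp.exact_count_pvalue(x, y, n1, n2)
            pl, _, _ = sp.exact_count_pvalue(y, x, n2, n1)
            assert pu - self._pmf(x, y, n1, n2) == pytest.approx(pl, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("x", [0, 1, 10, 100])
    @pytest.mark.parametrize("r", [0.5, 0.695926, 1.0, 2.0])
    def test_pmf_normalizes(self, x, r):
        """Sum over y of p(y|x) is 1 to 1e-12 (negative-binomial kernel)."""
        ys = np.arange(0, 5000)
        total = float(np.exp(logsumexp(_log_pmf(ys, x, math.log(r), math.log1p(r)))))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_scipy_negative_binomial(self, rng):
        """Independent route: the kernel is NB(x+1, N1/(N1+N2)) in y."""
        for _ in range(50):
            x = int(rng.integers(0, 200))
            y = int(rng.integers(0, 200))
            n1 = int(rng.integers(1000, 50_000))
            n2 = int(rng.integers(1000, 50_000))
            p = n1 / (n1 + n2)
            pl, pu, _ = sp.exact_count_pvalue(x, y, n1, n2)
            assert pl == pytest.approx(nbinom.cdf(y, x + 1, p), rel=1e-9, abs=1e-12)
            assert pu == pytest.approx(nbinom.sf(y - 1, x + 1, p), rel=1e-9, abs=1e-12)

    def test_large_counts_against_mpmath_oracle(self):
        """50-digit summation for the miR-9-5p worked pair (x=10, y=21 with
        the printed library totals)."""
        mpmath = pytest.importorskip("mpmath")
        mpmath.mp.dps = 50
        r = mpmath.mpf(N_TEST1) / N_CON1
        x = 10

        def pmf(y):
            return (
                r**y
                * mpmath.factorial(x + y)
                / (mpmath.factorial(x) * mpmath.factorial(y) * (1 + r) ** (x + y + 1))
            )

        upper = float(mpmath.fsum(pmf(y) for y in range(21, 400)))
        _pl, pu, _ = sp.exact_count_pvalue(10, 21, N_CON1, N_TEST1)
        assert pu == pytest.approx(upper, rel=1e-10)
        assert pu == pytest.approx(2.4e-3, rel=0.02)

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            sp.exact_count_pvalue(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            sp.exact_count_pvalue(0, 0, 0, 10)


class TestRunDE:
    def _table6_matrix(self):
        m = pd.DataFrame(
            {
                "CON1": [10, 2],
                "Test1": [21, 11],
            },
            index=["hsa-miR-9-5p", "hsa-miR-324-5p"],
        )
        return m, {"CON1": N_CON1, "Test1": N_TEST1}

    def test_mir9_worked_row(self):
        m, totals = self._table6_matrix()
        res = {r.mirna: r for r in sp.run_de(m, totals, "CON1", "Test1")}
        r = res["hsa-miR-9-5p"]
        assert r.log2fc == pytest.approx(1.5934, abs=1e-3)
        assert r.sig_label == "**"

    def test_mir324_test1_vs_test2_row(self):
        m = pd.DataFrame({"Test1": [11], "Test2": [3]}, index=["hsa-miR-324-5p"])
        cfg = DEConfig(min_pair_reads=0)
        (r,) = sp.run_de(m, {"Test1": N_TEST1, "Test2": N_TEST2}, "Test1", "Test2", cfg)
        assert r.log2fc == pytest.approx(-2.0936, abs=1e-3)
        assert r.p_reported == pytest.approx(0.016434, abs=2e-5)
        assert r.sig_label == "*"

    def test_low_pair_reads_abandoned(self):
        m = pd.DataFrame({"A": [6], "B": [7]}, index=["m1"])  # x+y = 13
        (r,) = sp.run_de(m, {"A": 10_000, "B": 10_000}, "A", "B")
        assert not r.tested and r.skip_reason == "low_expression"
        assert math.isnan(r.p_reported)

    def test_unknown_library_rejected(self):
        m, totals = self._table6_matrix()
        with pytest.raises(ValueError):
            sp.run_de(m, totals, "CON1", "nope")

    def test_output_sorted_by_pvalue(self, rng):
        m = pd.DataFrame(
            {"A": rng.integers(20, 2000, size=8), "B": rng.integers(20, 2000, size=8)},
            index=[f"m{i}" for i in range(8)],
        )
        res = sp.run_de(m, {"A": 100_000, "B": 120_000}, "A", "B")
        ps = [r.p_reported for r in res if r.tested]
        assert ps == sorted(ps)


class TestReplicates:
    def test_islet1_row(self):
        s = sp.summarize_replicates([28.24, 40.28, 52.76])
        assert s.mean == pytest.approx(40.426667, abs=1e-4)
        assert s.sem == pytest.approx(7.0786942, abs=1e-4)

    def test_smi32_row(self):
        s = sp.summarize_replicates([25.28, 18.36, 31.77])
        assert s.mean == pytest.approx(25.136667, abs=1e-4)
        assert s.sem == pytest.approx(3.8717969, abs=1e-4)

    def test_constant_values_zero_sem(self):
        s = sp.summarize_replicates([5, 5, 5])
        assert s.mean == 5 and s.sem == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sp.summarize_replicates([])


def _naive_average_linkage(dist: np.ndarray, names: list[str]):
    """O(n^3) reference implementation; returns merge records as
    (height, frozenset_of_leaves)."""
    clusters = {i: frozenset([i]) for i in range(len(names))}
    d = {
        (i, j): dist[i, j]
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    merges = []
    next_id = len(names)
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        new = clusters[i] | clusters[j]
        merges.append((h, frozenset(names[k] for k in new)))
        del d[(i, j)]
        for k in list(clusters):
            if k in (i, j):
                continue
            a = d.pop((min(i, k), max(i, k)))
            b = d.pop((min(j, k), max(j, k)))
            na, nb = len(clusters[i]), len(clusters[j])
            d[(min(k, next_id), max(k, next_id))] = (na * a + nb * b) / (na + nb)
        del clusters[i], clusters[j]
        clusters[next_id] = new
        next_id += 1
    return merges


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame(
            {"A": [10, 10, 50], "B": [20, 20, 10], "C": [40, 40, 5]},
            index=["m1", "m2", "m3"],
            dtype=float,
        )
        newick, Z, names = cluster_expression(m)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert "(m1:0,m2:0)" in newick.replace("0.0", "0") or "m1:0" in newick

    def test_correlated_pair_merges_before_anticorrelated(self):
        m = pd.DataFrame(
            {"A": [1, 2, 30], "B": [5, 10, 20], "C": [9, 18, 10]},
            index=["up1", "up2", "down"],
            dtype=float,
        )
        _, Z, names = cluster_expression(m)
        first = {names[int(Z[0, 0])], names[int(Z[0, 1])]}
        assert first == {"up1", "up2"}

    def test_matches_naive_average_linkage(self, rng):
        """Random 10x3 matrices: scipy tree equals the O(n^3) reference."""
        for _ in range(10):
            m = pd.DataFrame(
                rng.uniform(1, 1000, size=(10, 3)),
                index=[f"m{i}" for i in range(10)],
                columns=["A", "B", "C"],
            )
            _, Z, names = cluster_expression(m)
            vals = np.log2(m.sort_index().to_numpy() + 0.01)
            vals = vals - np.median(vals, axis=1, keepdims=True)
            dist = 1 - np.corrcoef(vals)
            np.fill_diagonal(dist, 0.0)
            expected = _naive_average_linkage(dist, names)
            # compare the merge heights and the leaf partition of every merge
            got = []
            members = {i: frozenset([names[i]]) for i in range(len(names))}
            for k, (a, b, h, _n) in enumerate(Z):
                new = members[int(a)] | members[int(b)]
                members[len(names) + k] = new
                got.append((h, new))
            for (h1, s1), (h2, s2) in zip(expected, got):
                assert h1 == pytest.approx(h2, abs=1e-9)
                assert s1 == s2

    def test_constant_row_distance_one(self, caplog):
        m = pd.DataFrame(
            {"A": [7, 1, 2], "B": [7, 5, 10], "C": [7, 9, 18]},
            index=["flat", "m1", "m2"],
            dtype=float,
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="srnapipe.diffexpr"):
            _, Z, names = cluster_expression(m)
        assert "constant" in caplog.text
        first = {names[int(Z[0, 0])], names[int(Z[0, 1])]}
        assert "flat" not in first

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            cluster_expression(pd.DataFrame({"A": [1.0]}, index=["m"]))


def test_count_matrix_round_trip(tmp_path):
    m = pd.DataFrame({"A": [3, 0], "B": [9, 4]}, index=["m1", "m2"])
    totals = {"A": 1000, "B": 2000}
    p = tmp_path / "counts.tsv"
    sp.write_count_matrix(p, m, totals)
    m2, totals2 = sp.read_count_matrix(p)
    assert totals2 == totals
    pd.testing.assert_frame_equal(m, m2, check_names=False)
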