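"""Stability statistics against naive brute-force oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

from mirnorm import stability as st

# ---------------------------------------------------------------------------
# independent naive oracles (plain loops, no shared code with the package)
# ---------------------------------------------------------------------------


def oracle_pairwise_sd(matrix: pd.DataFrame, j: str, k: str) -> float:
    diff = [matrix.loc[j, s] - matrix.loc[k, s] for s in matrix.columns]
    n = len(diff)
    mean = sum(diff) / n
    return (sum((d - mean) ** 2 for d in diff) / (n - 1)) ** 0.5


def oracle_genorm_m(matrix: pd.DataFrame) -> dict[str, float]:
    out = {}
    for j in matrix.index:
        sds = [oracle_pairwise_sd(matrix, j, k) for k in matrix.index if k != j]
        out[j] = sum(sds) / len(sds)
    return out


def oracle_bestkeeper(matrix: pd.DataFrame):
    import math

    index = {}
    for s in matrix.columns:
        logs = [math.log(matrix.loc[g, s]) for g in matrix.index]
        index[s] = math.exp(sum(logs) / len(logs))
    stats = {}
    for g in matrix.index:
        vals = [matrix.loc[g, s] for s in matrix.columns]
        n = len(vals)
        mean = sum(vals) / n
        sd = (sum((v - mean) ** 2 for v in vals) / (n - 1)) ** 0.5
        idx = [index[s] for s in matrix.columns]
        mi = sum(idx) / n
        num = sum((v - mean) * (i - mi) for v, i in zip(vals, idx))
        den = (sum((v - mean) ** 2 for v in vals) * sum((i - mi) ** 2 for i in idx)) ** 0.5
        stats[g] = {"sd": sd, "cv": 100 * sd / mean, "r": num / den}
    return index, stats


# ---------------------------------------------------------------------------


class TestGenorm:
    def test_constant_ratio_pair_minimal_equal_m(self):
        """Two genes at a constant offset have zero mutual ratio SD and tie."""
        rng = np.random.default_rng(0)
        a = 25.0 + rng.normal(0, 0.3, 6)
        m = pd.DataFrame(
            {"gA": a, "gB": a + 1.0, "gC": 28 + rng.normal(0, 0.5, 6)},
        ).T
        m.columns = [f"s{i}" for i in range(6)]
        res = st.genorm(m)
        assert res.m_values["gA"] == pytest.approx(res.m_values["gB"])
        assert res.m_values[["gA", "gB"]].max() < res.m_values["gC"]
        # their mutual contribution is exactly zero
        assert oracle_pairwise_sd(m, "gA", "gB") == pytest.approx(0.0, abs=1e-12)

    def test_m_matches_brute_force(self, toy_ct_matrix):
        res = st.genorm(toy_ct_matrix)
        expected = oracle_genorm_m(toy_ct_matrix)
        for g in toy_ct_matrix.index:
            assert res.m_values[g] == pytest.approx(expected[g], abs=1e-12)

    def test_noise_strictly_increases_m(self, toy_ct_matrix):
        """Injected noise on one gene raises its M in every seeded repeat."""
        base = st.genorm(toy_ct_matrix).m_values["gA"]
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = toy_ct_matrix.copy()
            noisy.loc["gA"] += rng.normal(0, 1.0, noisy.shape[1])
            assert st.genorm(noisy).m_values["gA"] > base

    def test_exclusion_order_and_ranking(self, simulated_dataset):
        from mirnorm import qpcr_preprocess as qp

        m, _ = qp.collapse_replicates(simulated_dataset)
        cal = qp.interrun_calibrate(m, simulated_dataset.meta)
        res = st.genorm(cal)
        assert res.exclusion_order[0] == "G5"  # planted unstable gene out first
        assert sorted(res.ranking[res.ranking == 1.5].index.tolist()) != []
        assert res.ranking.max() == len(cal.index)
        # V series has one entry per panel size from 2 to n-1
        assert len(res.v_series) == len(cal.index) - 2

    def test_sample_shift_invariance(self, toy_ct_matrix):
        """Adding a per-sample constant to all genes leaves M unchanged."""
        shifted = toy_ct_matrix + np.arange(toy_ct_matrix.shape[1]) * 0.7
        a = st.genorm(toy_ct_matrix).m_values
        b = st.genorm(shifted).m_values
        pd.testing.assert_series_equal(a, b, atol=1e-10, rtol=0)

    def test_too_few_genes_rejected(self, toy_ct_matrix):
        with pytest.raises(ValueError):
            st.genorm(toy_ct_matrix.iloc[:2])

    def test_missing_cells_rejected(self, toy_ct_matrix):
        bad = toy_ct_matrix.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            st.genorm(bad)


class TestNormfinder:
    def groups(self, matrix, n_tumor):
        return pd.Series(
            ["tumor"] * n_tumor + ["control"] * (matrix.shape[1] - n_tumor),
            index=matrix.columns,
        )

    def test_degenerate_stable_gene_attains_minimum(self):
        rng = np.random.default_rng(1)
        n = 12
        m = pd.DataFrame(
            {
                "stable": np.full(n, 25.0),
                "noisyA": 27 + rng.normal(0, 0.8, n),
                "noisyB": 24 + rng.normal(0, 0.8, n),
                "noisyC": 30 + rng.normal(0, 0.8, n),
            }
        ).T
        m.columns = [f"s{i}" for i in range(n)]
        rho = st.normfinder(m, self.groups(m, 6))
        assert rho.idxmin() == "stable"

    def test_planted_group_effect_largest_rho(self):
        """A 2-cycle group shift dominates the stability value (99/100 seeds)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 30
            data = {f"g{i}": 24.0 + i + rng.normal(0, 0.3, 2 * n) for i in range(4)}
            m = pd.DataFrame(data).T
            m.columns = [f"s{i}" for i in range(2 * n)]
            m.loc["g3", m.columns[:n]] += 2.0
            rho = st.normfinder(m, self.groups(m, n))
            hits += rho.idxmax() == "g3"
        assert hits >= 99

    def test_identical_groups_reduce_to_group_free_ordering(self, toy_ct_matrix):
        doubled = pd.concat([toy_ct_matrix, toy_ct_matrix], axis=1)
        doubled.columns = [f"s{i}" for i in range(doubled.shape[1])]
        groups = self.groups(doubled, toy_ct_matrix.shape[1])
        rho_grouped = st.normfinder(doubled, groups)
        rho_free = st.normfinder(doubled)
        assert list(rho_grouped.sort_values().index) == list(rho_free.sort_values().index)

    def test_empty_group_rejected(self, toy_ct_matrix):
        groups = pd.Series("tumor", index=toy_ct_matrix.columns)
        with pytest.raises(ValueError):
            st.normfinder(toy_ct_matrix, groups)

    def test_rho_nonnegative(self, toy_ct_matrix):
        rho = st.normfinder(toy_ct_matrix, self.groups(toy_ct_matrix, 2))
        assert (rho >= 0).all()


class TestBestkeeper:
    def test_constant_gene_sd_cv_zero(self):
        m = pd.DataFrame(
            {"s1": [25.0, 28.1], "s2": [25.0, 27.6], "s3": [25.0, 28.4]},
            index=["const", "var"],
        )
        res = st.bestkeeper(m)
        assert res.table.loc["const", "sd"] == 0.0
        assert res.table.loc["const", "cv_percent"] == 0.0
        assert np.isnan(res.table.loc["const", "r"])
        # still ranked best by SD
        assert res.table["sd"].idxmin() == "const"

    def test_matches_brute_force(self, toy_ct_matrix):
        res = st.bestkeeper(toy_ct_matrix)
        index, expected = oracle_bestkeeper(toy_ct_matrix)
        for s in toy_ct_matrix.columns:
            assert res.index[s] == pytest.approx(index[s], abs=1e-12)
        for g in toy_ct_matrix.index:
            assert res.table.loc[g, "sd"] == pytest.approx(expected[g]["sd"], abs=1e-12)
            assert res.table.loc[g, "cv_percent"] == pytest.approx(expected[g]["cv"], abs=1e-12)
            assert res.table.loc[g, "r"] == pytest.approx(expected[g]["r"], abs=1e-12)

    def test_duplicating_gene_leaves_sd_unchanged(self, toy_ct_matrix):
        dup = pd.concat([toy_ct_matrix, toy_ct_matrix.loc[["gA"]].rename(index={"gA": "gA2"})])
        a = st.bestkeeper(toy_ct_matrix).table.loc["gA", "sd"]
        b = st.bestkeeper(dup).table.loc["gA", "sd"]
        assert a == pytest.approx(b, abs=1e-14)


class TestDeltactStability:
    def test_constant_offset_pair_zero(self):
        m = pd.DataFrame(
            {"s1": [25.0, 26.0], "s2": [25.7, 26.7], "s3": [24.9, 25.9]},
            index=["gA", "gB"],
        )
        out = st.deltact_stability(m)
        assert out["gA"] == pytest.approx(0.0, abs=1e-12)
        assert out["gB"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, toy_ct_matrix):
        out = st.deltact_stability(toy_ct_matrix)
        for j in toy_ct_matrix.index:
            sds = [
                oracle_pairwise_sd(toy_ct_matrix, j, k)
                for k in toy_ct_matrix.index if k != j
            ]
            assert out[j] == pytest.approx(sum(sds) / len(sds), abs=1e-12)

    def test_sample_permutation_invariance(self, toy_ct_matrix):
        rng = np.random.default_rng(5)
        perm = rng.permutation(toy_ct_matrix.columns)
        a = st.deltact_stability(toy_ct_matrix)
        b = st.deltact_stability(toy_ct_matrix[perm])
        pd.testing.assert_series_equal(a, b, atol=1e-12, rtol=0)

    def test_single_gene_rejected(self, toy_ct_matrix):
        with pytest.raises(ValueError):
            st.deltact_stability(toy_ct_matrix.iloc[:1])


def test_all_methods_sample_permutation_invariant(toy_ct_matrix):
    rng = np.random.default_rng(9)
    perm = list(rng.permutation(toy_ct_matrix.columns))
    shuffled = toy_ct_matrix[perm]
    groups = pd.Series(["tumor", "tumor", "control", "control", "control"],
                       index=toy_ct_matrix.columns)
    a = st.stability_report(toy_ct_matrix, groups).table
    b = st.stability_report(shuffled, groups.loc[perm]).table
    pd.testing.assert_frame_equal(a, b, atol=1e-10, rtol=0)
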