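import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from deltascan import stats as st
from deltascan import synthetic as syn


def members_frame(rows):
    return pd.DataFrame(rows, columns=[
        "protein", "site", "cluster_center", "sample_id"])


class TestAggregateSites:
    def test_counting(self):
        members = members_frame([
            ("P1", 10, 15.9949, "T01"),
            ("P1", 10, 15.9949, "T01"),
            ("P1", 10, 15.9949, "N01"),
        ])
        table = st.aggregate_sites(members)
        assert len(table) == 1
        assert table.loc[("P1", 10, 15.9949)].tolist() == [1, 2]

    def test_empty(self):
        table = st.aggregate_sites(members_frame([]))
        assert table.empty

    def test_conservation_random(self):
        rng = np.random.default_rng(0)
        members = members_frame([
            (f"P{rng.integers(3)}", int(rng.integers(1, 5)),
             float(rng.choice([1.0, 2.0])), f"S{rng.integers(4)}")
            for _ in range(500)])
        table = st.aggregate_sites(members)
        assert int(table.to_numpy().sum()) == 500

    def test_planted_site_totals_match_generator(self):
        peak = syn.PeakSpec(true_delta=15.9949, n_psms=300, mass_sd=0.002,
                            site_pool=(("P1", 10), ("P2", 20)))
        psms = syn.generate_psm_table([peak], syn.CohortSpec(seed=1))
        psms = psms.assign(cluster_center=15.9949)
        table = st.aggregate_sites(psms)
        assert int(table.to_numpy().sum()) == 300
        by_site = psms.groupby(["protein", "site"]).size()
        for (protein, site), count in by_site.items():
            assert table.loc[(protein, site, 15.9949)].sum() == count


def paired_table(tumor, nat):
    """Build a 1-row site table with given per-pair counts."""
    n = len(tumor)
    data = {}
    for i in range(n):
        data[f"T{i:02d}"] = [tumor[i]]
        data[f"N{i:02d}"] = [nat[i]]
    index = pd.MultiIndex.from_tuples([("P1", 10, 15.9949)],
                                      names=["protein", "site",
                                             "cluster_center"])
    return pd.DataFrame(data, index=index)


def pairing(n):
    return [(f"T{i:02d}", f"N{i:02d}") for i in range(n)]


class TestDifferentialModification:
    def test_identical_vectors_null(self):
        table = paired_table([5, 8, 3, 9], [5, 8, 3, 9])
        result = st.differential_modification(table, pairing(4),
                                              normalization="sample")
        assert result.loc[0, "log2_fold_change"] == pytest.approx(0.0)
        assert result.loc[0, "p_value"] == 1.0

    def test_single_pair_flagged_untested(self):
        table = paired_table([5], [1])
        result = st.differential_modification(table, pairing(1))
        assert not result.loc[0, "tested"]
        assert np.isnan(result.loc[0, "p_value"])

    def test_all_zero_row_flagged(self):
        table = paired_table([0, 0, 0], [0, 0, 0])
        result = st.differential_modification(table, pairing(3))
        assert result.loc[0, "all_zero"]
        assert not result.loc[0, "tested"]

    def test_unpaired_sample_named(self):
        table = paired_table([1, 2], [3, 4])
        with pytest.raises(ValueError, match="T99"):
            st.differential_modification(table, [("T99", "N00")])

    def test_fold_change_antisymmetry(self):
        rng = np.random.default_rng(2)
        table = paired_table(list(rng.integers(1, 30, 6)),
                             list(rng.integers(1, 30, 6)))
        forward = st.differential_modification(table, pairing(6),
                                               normalization="sample")
        swapped = st.differential_modification(
            table, [(n, t) for t, n in pairing(6)], normalization="sample")
        assert forward.loc[0, "log2_fold_change"] == pytest.approx(
            -swapped.loc[0, "log2_fold_change"])

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(3)
        n_rows, n_pairs = 12, 8
        data = {}
        for i in range(n_pairs):
            data[f"T{i:02d}"] = rng.integers(0, 40, n_rows)
            data[f"N{i:02d}"] = rng.integers(0, 40, n_rows)
        index = pd.MultiIndex.from_tuples(
            [("P1", s, 1.0) for s in range(n_rows)],
            names=["protein", "site", "cluster_center"])
        table = pd.DataFrame(data, index=index)
        result = st.differential_modification(table, pairing(n_pairs),
                                              normalization="sample")
        tested = result[result.tested].sort_values("p_value")
        q = tested["q_value"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()

    def test_power_planted_enrichment(self):
        """4x tumor enrichment at one site recovered at q < 0.05."""
        hits = 0
        n_reps = 20
        for seed in range(n_reps):
            rng = np.random.default_rng(100 + seed)
            n_pairs = 20
            data = {}
            base = 25
            for i in range(n_pairs):
                data[f"T{i:02d}"] = [rng.poisson(base * 4)] + list(
                    rng.poisson(base, 3))
                data[f"N{i:02d}"] = list(rng.poisson(base, 4))
            index = pd.MultiIndex.from_tuples(
                [("P1", s, 1.0) for s in (10, 20, 30, 40)],
                names=["protein", "site", "cluster_center"])
            table = pd.DataFrame(data, index=index)
            result = st.differential_modification(table, pairing(n_pairs),
                                                  normalization="sample")
            row = result[(result.site == 10)]
            hits += float(row["q_value"].iloc[0]) < 0.05
        assert hits >= 0.9 * n_reps


class TestCorrelationMatrix:
    def make_table(self, values):
        index = pd.MultiIndex.from_tuples(
            [("P1", i, 1.0) for i in range(len(values))],
            names=["protein", "site", "cluster_center"])
        return pd.DataFrame(values, index=index,
                            columns=[f"S{j}" for j in
                                     range(len(values[0]))])

    def test_monotone_transform_perfect_rho(self):
        base = [1.0, 4.0, 2.0, 8.0, 5.0]
        table = self.make_table([base, [v ** 3 for v in base]])
        rho, _ = st.correlation_matrix(table)
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        base = [1.0, 4.0, 2.0, 8.0, 5.0]
        table = self.make_table([base, [-v for v in base]])
        rho, _ = st.correlation_matrix(table)
        assert rho.iloc[0, 1] == pytest.approx(-1.0)

    def test_independent_rows_near_zero(self):
        rng = np.random.default_rng(4)
        table = self.make_table([list(rng.normal(size=1000)),
                                 list(rng.normal(size=1000))])
        rho, p = st.correlation_matrix(table)
        assert abs(rho.iloc[0, 1]) < 0.1
        assert p.iloc[0, 1] > 0.01

    def test_constant_row_reported_missing(self):
        table = self.make_table([[1.0, 1.0, 1.0, 1.0],
                                 [1.0, 2.0, 3.0, 4.0]])
        rho, _ = st.correlation_matrix(table)
        assert np.isnan(rho.iloc[0, 1])
        assert rho.iloc[1, 1] == 1.0

    def test_symmetry_unit_diagonal_bounds(self):
        rng = np.random.default_rng(5)
        table = self.make_table([list(rng.normal(size=8))
                                 for _ in range(5)])
        rho, _ = st.correlation_matrix(table)
        arr = rho.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.allclose(np.diag(arr), 1.0)
        assert np.nanmax(np.abs(arr)) <= 1.0 + 1e-12

    def test_too_few_samples_rejected(self):
        table = self.make_table([[1.0, 2.0]])
        with pytest.raises(ValueError, match="samples"):
            st.correlation_matrix(table)


class TestLogrank:
    def test_matches_lifelines(self):
        for seed in range(5):
            table = syn.generate_survival_table(80, 2.0, seed=seed)
            group = (table["marker"] > table["marker"].median()).to_numpy()
            mine = st.logrank_statistic(table["time"], table["event"], group)
            ref = logrank_test(
                table.loc[group, "time"], table.loc[~group, "time"],
                table.loc[group, "event"], table.loc[~group, "event"])
            assert mine == pytest.approx(ref.test_statistic, abs=1e-8)

    def test_identical_groups_statistic_zero(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        group = np.array([True, True, True, False, False, False])
        assert st.logrank_statistic(time, event, group) == pytest.approx(0.0)


class TestOptimalCutpoint:
    def brute_force(self, table, scan_range=(0.10, 0.90)):
        marker = table["marker"].to_numpy()
        lo, hi = np.quantile(marker, scan_range)
        best_stat, best_cut = -1.0, None
        for cut in np.unique(marker):
            if not (lo <= cut <= hi) or cut >= marker.max():
                continue
            group = marker > cut
            stat = logrank_test(
                table.loc[group, "time"], table.loc[~group, "time"],
                table.loc[group, "event"], table.loc[~group, "event"]
            ).test_statistic
            if stat > best_stat:
                best_stat, best_cut = stat, cut
        return best_cut, best_stat

    def test_twelve_patient_fixture_matches_exhaustive_oracle(self):
        table = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(12)],
            "time": [5.0, 8.0, 3.0, 12.0, 2.0, 9.0, 7.0, 1.5, 11.0, 4.0,
                     6.0, 10.0],
            "event": [1, 0, 1, 0, 1, 1, 0, 1, 0, 1, 1, 0],
            "marker": [2.1, 0.3, 3.5, 0.1, 4.2, 0.8, 1.9, 5.0, 0.2, 2.8,
                       3.1, 0.5],
        })
        result = st.optimal_cutpoint_survival(table)
        oracle_cut, oracle_stat = self.brute_force(table)
        assert result.cutpoint == pytest.approx(oracle_cut)
        assert result.statistic == pytest.approx(oracle_stat, abs=1e-8)
        assert result.n_low + result.n_high == 12

    def test_oracle_equivalence_random_small_tables(self):
        for seed in range(5):
            table = syn.generate_survival_table(40, 2.0, seed=seed)
            result = st.optimal_cutpoint_survival(table)
            oracle_cut, oracle_stat = self.brute_force(table)
            assert result.cutpoint == pytest.approx(oracle_cut)
            assert result.statistic == pytest.approx(oracle_stat, abs=1e-8)

    def test_identical_curves_zero_statistic(self):
        # marker duplicates an identical survival pattern in both halves
        table = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(8)],
            "time": [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 0, 1, 1, 1, 0],
            "marker": [0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0],
        })
        result = st.optimal_cutpoint_survival(table, scan_range=(0.0, 1.0))
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_null_permutation_p_calibrated(self):
        rejections = 0
        n_reps = 60
        for seed in range(n_reps):
            table = syn.generate_survival_table(120, 1.0, seed=5000 + seed)
            result = st.optimal_cutpoint_survival(table, n_permutations=99,
                                                  seed=seed)
            rejections += result.p_adjusted <= 0.05
        assert 0.0 <= rejections / n_reps <= 0.12

    def test_all_censored_rejected(self):
        table = pd.DataFrame({
            "patient_id": ["P1", "P2", "P3"], "time": [1.0, 2.0, 3.0],
            "event": [0, 0, 0], "marker": [0.1, 0.5, 0.9]})
        with pytest.raises(ValueError, match="event"):
            st.optimal_cutpoint_survival(table)

    def test_constant_marker_rejected(self):
        table = pd.DataFrame({
            "patient_id": ["P1", "P2", "P3", "P4"],
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 0], "marker": [0.5] * 4})
        with pytest.raises(ValueError, match="constant"):
            st.optimal_cutpoint_survival(table)

    def test_naive_p_matches_chi2_tail(self):
        from scipy.stats import chi2
        table = syn.generate_survival_table(50, 3.0, seed=9)
        result = st.optimal_cutpoint_survival(table)
        assert result.p_value == pytest.approx(
            chi2.sf(result.statistic, df=1))
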