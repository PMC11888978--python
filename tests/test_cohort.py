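import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hepzone as hz
from hepzone.cohort import compare_groups, repeated_measures, simulate_endpoints
from hepzone.profiles import builtin_profiles, get_profile


@pytest.fixture(scope="module")
def phx_profiles():
    return [p for p in builtin_profiles().values() if p.group.startswith("PHx")]


class TestSimulateEndpoints:
    def test_deterministic_given_seed(self, phx_profiles):
        a = simulate_endpoints(phx_profiles, n_per_group=6, seed=3)
        b = simulate_endpoints(phx_profiles, n_per_group=6, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_no_duplicate_mouse_days(self, phx_profiles):
        table = simulate_endpoints(phx_profiles, n_per_group=6, seed=1)
        assert not table.duplicated(["mouse_id", "day"]).any()
        assert (table["rlw_bw_pct"] > 0).all()

    def test_large_sample_means_match_profiles(self, phx_profiles):
        # law of large numbers: sample means converge on the profile means
        table = simulate_endpoints(phx_profiles, n_per_group=10_000, seed=8)
        for group, day, endpoint in [
            ("PHx+Gln", 2, "rlw_bw_pct"),
            ("PHx+Gln", 2, "pcna_pct"),
            ("PHx-Gln", 4, "rlw_bw_pct"),
            ("PHx+Gln", 1, "ast_UL"),  # log-normal, mean-matched
        ]:
            stat = get_profile(group, day).endpoint_means[endpoint]
            vals = table.loc[
                (table["group"] == group) & (table["day"] == day), endpoint
            ].to_numpy()
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - stat.mean) <= 3 * se

    def test_transaminases_positive_and_skewed(self, phx_profiles):
        table = simulate_endpoints(phx_profiles, n_per_group=2000, seed=4)
        d1 = table[(table["group"] == "PHx+Gln") & (table["day"] == 1)]
        assert (d1["ast_UL"] > 0).all()
        assert stats.skew(d1["ast_UL"]) > 0

    def test_shared_intercept_induces_within_mouse_correlation(self, phx_profiles):
        table = simulate_endpoints(phx_profiles, n_per_group=500, seed=5, icc=0.8)
        wide = table.pivot(index="mouse_id", columns="day", values="albumin")
        corr = wide.corr().to_numpy()
        off_diag = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert off_diag.mean() > 0.5

    def test_rejects_tiny_groups(self, phx_profiles):
        with pytest.raises(ValueError):
            simulate_endpoints(phx_profiles, n_per_group=1, seed=0)


class TestCompareGroups:
    def test_identical_groups_null_result(self):
        rows = []
        vals = [3.1, 2.9, 3.0, 3.2, 2.8, 3.0]
        for g in ("PHx+Gln", "PHx-Gln"):
            for i, v in enumerate(vals):
                rows.append(
                    {"mouse_id": f"{g}/{i}", "group": g, "day": 2, "rlw_bw_pct": v}
                )
        cmp = compare_groups(pd.DataFrame(rows), "rlw_bw_pct", 2)
        assert cmp.statistic == 0.0
        assert cmp.p_value == pytest.approx(1.0)
        assert cmp.stars == "ns"

    def test_day2_separation_detected_with_power(self, phx_profiles):
        # Monte-Carlo power oracle for the printed day-2 liver-weight contrast
        hits = 0
        reps = 200
        for rep in range(reps):
            table = simulate_endpoints(phx_profiles, n_per_group=6, seed=10_000 + rep)
            cmp = compare_groups(table, "rlw_bw_pct", 2)
            hits += cmp.p_value < 0.05
        assert hits / reps >= 0.80

    def test_three_groups_tukey_flags_shifted_group(self):
        rng = np.random.default_rng(0)
        rows = []
        for g, mu in (("sham+Gln", 4.3), ("sham-Gln", 4.3), ("PHx-Gln", 2.0)):
            for i in range(30):
                rows.append(
                    {"mouse_id": f"{g}/{i}", "group": g, "day": 2,
                     "rlw_bw_pct": mu + rng.normal(0, 0.3)}
                )
        cmp = compare_groups(pd.DataFrame(rows), "rlw_bw_pct", 2)
        assert cmp.method == "anova_tukey"
        tk = cmp.tukey.set_index(["group1", "group2"])
        flagged = tk[tk["reject"] == True]  # noqa: E712
        assert len(flagged) == 2
        assert all("PHx-Gln" in idx for idx in flagged.index)

    def test_insufficient_replication_rejected(self):
        rows = [
            {"mouse_id": "a", "group": "PHx+Gln", "day": 2, "rlw_bw_pct": 3.0},
            {"mouse_id": "b", "group": "PHx-Gln", "day": 2, "rlw_bw_pct": 2.0},
            {"mouse_id": "c", "group": "PHx-Gln", "day": 2, "rlw_bw_pct": 2.1},
        ]
        with pytest.raises(ValueError):
            compare_groups(pd.DataFrame(rows), "rlw_bw_pct", 2)


class TestRepeatedMeasures:
    def test_group_effect_detected_in_majority_of_reps(self, phx_profiles):
        hits = 0
        reps = 20
        for rep in range(reps):
            table = simulate_endpoints(phx_profiles, n_per_group=6, seed=500 + rep)
            res = repeated_measures(table, "rlw_bw_pct")
            hits += res.p_value < 0.05
        assert hits > reps / 2

    def test_single_day_data_rejected(self, phx_profiles):
        table = simulate_endpoints(phx_profiles, n_per_group=6, seed=0)
        with pytest.raises(ValueError):
            repeated_measures(table[table["day"] == 2], "rlw_bw_pct")

    def test_null_pvalues_approximately_uniform(self):
        # no group separation: LRT p-values should be uniform (KS check)
        base = get_profile("sham+Gln", 0)
        profiles = [
            base.with_(group=g, day=d)
            for g in ("sham+Gln", "sham-Gln")
            for d in (0, 2, 6)
        ]
        pvals = []
        for rep in range(150):
            table = simulate_endpoints(profiles, n_per_group=6, seed=3_000 + rep)
            pvals.append(repeated_measures(table, "albumin").p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
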