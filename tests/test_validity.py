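"""Spearman panel, nonparametric group tests and the threshold odds ratio."""

import itertools
import math

import numpy as np
import pytest

from aspos.errors import InvalidInputError, UndefinedStatisticError
from aspos.validity import (
    kruskal_wallis,
    mann_whitney,
    odds_ratio,
    spearman,
    threshold_analysis,
    validity_report,
)

# --- independent oracles -------------------------------------------------


def midranks(v):
    v = list(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = midranks(x), midranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def kruskal_oracle(groups):
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    return h / (1 - tie / (n**3 - n)) if tie else h


def u_oracle(x, y):
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 8, 16, 32]).rho == pytest.approx(1.0)
        assert spearman(x, [10, 8, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_tied_fixture_matches_midrank_pearson_oracle(self):
        x = [1, 2, 2, 3, 3, 3, 4, 5]
        y = [0, 1, 1, 1, 2, 4, 4, 6]
        assert spearman(x, y).rho == pytest.approx(spearman_oracle(x, y), rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_random_tied_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, 25)
        y = np.clip(x + rng.integers(-2, 3, 25), 0, 8)
        if len(set(x.tolist())) < 2 or len(set(y.tolist())) < 2:
            pytest.skip("degenerate draw")
        assert spearman(x, y).rho == pytest.approx(
            spearman_oracle(x.tolist(), y.tolist()), rel=1e-10
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, rel=1e-12)
        assert spearman(x, y**3).rho == pytest.approx(base, rel=1e-12)

    def test_constant_variable_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestKruskalWallis:
    def test_all_identical_gives_zero(self):
        res = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_ranked_two_groups(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        # ranks 1..6, R1=6, R2=15: H = 12/(6*7)*(12+75) - 21
        assert res.statistic == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_tie_corrected_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 5, rng.integers(4, 9)).tolist() for _ in range(3)]
        pooled = [v for g in groups for v in g]
        if len(set(pooled)) < 2:
            pytest.skip("degenerate draw")
        assert kruskal_wallis(groups).statistic == pytest.approx(
            kruskal_oracle(groups), rel=1e-10
        )

    def test_two_group_h_equals_mann_whitney_z_squared(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.integers(0, 6, 20)
            y = rng.integers(1, 8, 25)
            h = kruskal_wallis([x, y])
            u = mann_whitney(x, y, exact_max_n=0)
            mu = len(x) * len(y) / 2
            n = len(x) + len(y)
            _, t = np.unique(np.concatenate([x, y]), return_counts=True)
            var = len(x) * len(y) / 12 * ((n + 1) - (t**3 - t).sum() / (n * (n - 1)))
            z2 = (u.statistic - mu) ** 2 / var
            assert h.statistic == pytest.approx(z2, rel=1e-9)
            assert h.p_value == pytest.approx(u.p_value, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            kruskal_wallis([[1, 2], []])


class TestMannWhitney:
    def test_complete_separation(self):
        assert mann_whitney([1, 2], [3, 4]).statistic == 0.0

    def test_identical_multisets_give_half_product(self):
        x = [1, 2, 3, 4]
        res = mann_whitney(x, list(x))
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 4).tolist()
        y = rng.integers(0, 5, 4).tolist()
        res = mann_whitney(x, y)
        assert res.method == "mann-whitney-exact"
        # independent enumeration over all C(8,4) labelings
        pooled = x + y
        mu = len(x) * len(y) / 2
        obs = abs(u_oracle(x, y) - mu)
        hits = total = 0
        for comb in itertools.combinations(range(8), 4):
            xs = [pooled[i] for i in comb]
            ys = [pooled[i] for i in range(8) if i not in comb]
            total += 1
            if abs(u_oracle(xs, ys) - mu) >= obs - 1e-12:
                hits += 1
        assert res.statistic == pytest.approx(u_oracle(x, y), rel=1e-12)
        assert res.p_value == pytest.approx(hits / total, rel=1e-12)

    def test_large_sample_p_matches_scipy_asymptotic(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(2)
        x = rng.integers(0, 10, 30)
        y = rng.integers(2, 12, 28)
        res = mann_whitney(x, y)
        ref = mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            mann_whitney([], [1, 2])


class TestOddsRatio:
    def test_symmetric_table_is_one(self):
        res = odds_ratio(2, 2, 2, 2)
        assert res.or_estimate == pytest.approx(1.0)
        assert not res.correction_applied

    def test_cross_product(self):
        assert odds_ratio(10, 5, 2, 20).or_estimate == pytest.approx(20.0)

    def test_zero_cell_haldane_anscombe(self):
        res = odds_ratio(5, 4, 0, 86)
        assert res.correction_applied
        assert res.or_estimate == pytest.approx((5.5 * 86.5) / (4.5 * 0.5), rel=1e-12)
        se = math.sqrt(1 / 5.5 + 1 / 4.5 + 1 / 0.5 + 1 / 86.5)
        assert res.ci_low == pytest.approx(res.or_estimate * math.exp(-1.959963984540054 * se), rel=1e-9)
        assert res.ci_high == pytest.approx(res.or_estimate * math.exp(1.959963984540054 * se), rel=1e-9)
        assert res.ci_low <= res.or_estimate <= res.ci_high
        assert 0 < res.p_value < 0.05

    def test_no_correction_when_all_cells_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b, c, d = rng.integers(1, 30, 4)
            res = odds_ratio(a, b, c, d)
            assert not res.correction_applied
            assert res.or_estimate == pytest.approx(a * d / (b * c), rel=1e-12)

    def test_zero_margin_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            odds_ratio(0, 0, 3, 4)

    def test_negative_cell_rejected(self):
        with pytest.raises(InvalidInputError):
            odds_ratio(-1, 2, 3, 4)


class TestThresholdAnalysis:
    @staticmethod
    def published_partition():
        """Severity partition with the development study's group counts."""
        totals = [1] * 43 + [2] * 43 + [3] * 9 + [5] * 31
        nihss = (
            [1] * 43 + [2] * 43  # LOW: nobody at >= 6
            + [7] * 5 + [3] * 4  # INTERMEDIATE: 5 of 9 severe
            + [8] * 26 + [4] * 5  # HIGH: 26 of 31 severe
        )
        return totals, nihss

    def test_published_partition_reconstruction(self):
        totals, nihss = self.published_partition()
        res = threshold_analysis(totals, nihss)
        g = res.groups.set_index("group")
        assert g.loc["LOW", "n"] == 86 and g.loc["LOW", "n_severe"] == 0
        assert g.loc["INTERMEDIATE", "n"] == 9 and g.loc["INTERMEDIATE", "n_severe"] == 5
        assert g.loc["HIGH", "n"] == 31 and g.loc["HIGH", "n_severe"] == 26
        assert g["n"].sum() == 126
        assert g.loc["LOW", "pct"] == pytest.approx(100 * 86 / 126)
        assert g.loc["INTERMEDIATE", "pct"] == pytest.approx(100 * 9 / 126)
        assert g.loc["HIGH", "pct"] == pytest.approx(100 * 31 / 126)
        orr = res.odds_intermediate_vs_low
        assert orr.correction_applied
        assert orr.or_estimate == pytest.approx((5.5 * 86.5) / (4.5 * 0.5), rel=1e-12)
        assert res.kruskal.statistic > 0 and res.kruskal.p_value < 1e-4

    def test_degenerate_single_group(self):
        res = threshold_analysis([1, 2, 1, 2, 1], [1, 2, 3, 1, 2])
        assert list(res.groups["group"]) == ["LOW"]
        assert res.odds_intermediate_vs_low is None
        assert any("INTERMEDIATE" in w or "empty" in w for w in res.warnings)

    def test_group_counts_always_sum_to_n(self):
        rng = np.random.default_rng(7)
        totals = rng.integers(0, 12, 80)
        nihss = rng.integers(0, 20, 80)
        res = threshold_analysis(totals, nihss)
        assert res.groups["n"].sum() == 80

    def test_simulated_cohort_positive_association(self, big_cohort):
        totals = big_cohort.totals()
        nihss = big_cohort.companion("NIHSS", 1)
        res = threshold_analysis(totals.to_numpy(), nihss.to_numpy())
        assert res.odds_intermediate_vs_low.or_estimate > 1
        assert res.kruskal.p_value < 1e-10


class TestValidityReport:
    def test_panel_has_eight_rows(self, default_cohort):
        panel = validity_report(default_cohort)
        assert len(panel) == 8
        assert set(panel["day"]) == {1, 90}
        assert list(panel[panel["day"] == 90]["scale"]) == ["NIHSS", "Barthel", "mRS"]

    def test_exact_monotone_companions_recover_latent_rank_correlation(self):
        # replace every companion with a strictly monotone transform of the
        # latent trait: by monotone invariance each panel |rho| must equal
        # spearman(total, theta) exactly, with the transform's sign
        import pandas as pd

        from aspos.simulate import default_params, generate_cohort

        cohort = generate_cohort(default_params(
            seed=6, n_patients=400, item_noise_sd=0.0, offscale_prob=0.0,
            rater_disagreement=0.0, retest_disagreement=0.0))
        signs = {"NIHSS": 1, "mRS": 1, "IVBSS": 1, "Barthel": -1, "GCS": -1}
        frames = []
        for day in (1, 90):
            for name, s in signs.items():
                frames.append(pd.DataFrame({
                    "patient_id": cohort.consensus.index,
                    "day": day,
                    "scale": name,
                    "value": s * np.exp(cohort.theta),
                }))
        cohort.companions = pd.concat(frames, ignore_index=True)
        panel = validity_report(cohort)
        ref = spearman(cohort.totals().to_numpy(), cohort.theta).rho
        for _, row in panel.iterrows():
            assert row["rho"] == pytest.approx(signs[row["scale"]] * ref, rel=1e-12)

    def test_default_cohort_signs(self, big_cohort):
        panel = validity_report(big_cohort).set_index(["scale", "day"])
        assert panel.loc[("NIHSS", 1), "rho"] > 0.7
        assert panel.loc[("Barthel", 1), "rho"] < 0
        assert panel.loc[("GCS", 1), "rho"] < 0
        assert panel.loc[("NIHSS", 90), "rho"] > 0.5
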