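"""Rank-statistics kernel against brute-force oracles; structure diagnostics."""

import math

import numpy as np
import pytest

from mirpanel import (
    CtMatrix,
    SampleAnnotation,
    ValidationError,
    correlation_profiles,
    dunn_posthoc,
    group_quantity_trend,
    kruskal_wallis,
    local_vs_global_slope,
    spearman,
)
from mirpanel.coregulation import ConstantInputWarning
from mirpanel.simulate import SyntheticConfig, generate_cohort


# ---------------------------------------------------------------------------
# independent oracles (no scipy.stats.rankdata)
# ---------------------------------------------------------------------------

def average_ranks(values):
    """Average ranks computed by explicit sorting and tie-group walking."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman_r(x, y):
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def oracle_kruskal_h(values, groups):
    ranks = average_ranks(list(values))
    n = len(values)
    uniq = sorted(set(groups))
    h = 0.0
    for g in uniq:
        rg = [r for r, gg in zip(ranks, groups) if gg == g]
        h += (sum(rg) ** 2) / len(rg)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in values:
        ties[v] = ties.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction


def oracle_dunn_z(values, groups, a, b):
    ranks = average_ranks(list(values))
    n = len(values)
    ties = {}
    for v in values:
        ties[v] = ties.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in ties.values()) / (12.0 * (n - 1))
    ra = [r for r, g in zip(ranks, groups) if g == a]
    rb = [r for r, g in zip(ranks, groups) if g == b]
    se = math.sqrt(
        (n * (n + 1) / 12.0 - tie_term) * (1.0 / len(ra) + 1.0 / len(rb))
    )
    return (sum(ra) / len(ra) - sum(rb) / len(rb)) / se


class TestSpearman:
    def test_strictly_increasing_is_one(self):
        r, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)

    def test_strictly_decreasing_is_minus_one(self):
        r, _ = spearman([1, 2, 3, 4], [5, 4, 3, 2])
        assert r == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rank_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=9).astype(float)  # forces ties
        y = rng.normal(size=9)
        if np.ptp(x) == 0:
            x[0] += 1
        r, _ = spearman(x, y)
        assert r == pytest.approx(oracle_spearman_r(x, y), abs=1e-12)

    def test_constant_input_flagged_not_zero(self):
        with pytest.warns(ConstantInputWarning):
            r, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(r) and math.isnan(p)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1.0, 2.0], [1.0, 2.0])


class TestKruskalWallis:
    def test_identical_observations_degenerate(self):
        h, p = kruskal_wallis([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert h == 0.0 and p == 1.0

    def test_three_groups_match_rank_sum_formula(self):
        values = [1.0, 5.0, 9.0, 2.0, 6.0, 7.0, 3.0, 4.0, 8.0]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        h, _ = kruskal_wallis(values, groups)
        assert h == pytest.approx(oracle_kruskal_h(values, groups), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_tied_data_match_corrected_formula(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 5, size=15).astype(float)
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        if np.ptp(values) == 0:
            values[0] += 1
        h, _ = kruskal_wallis(values, groups)
        assert h == pytest.approx(oracle_kruskal_h(values, groups), abs=1e-10)

    def test_p_decreases_with_shift_size(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, size=30)
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        ps = []
        for shift in (0.5, 1.5, 3.0):
            values = base.copy()
            values[10:20] += shift
            values[20:] += 2 * shift
            ps.append(kruskal_wallis(values, groups)[1])
        assert ps[0] > ps[1] > ps[2]


class TestDunn:
    def test_identical_groups_give_zero_z_unit_p(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 9.0, 9.5, 10.0]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = dunn_posthoc(values, groups, [("a", "b")])
        z, p = res[("a", "b")]
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_z_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 8, size=14).astype(float)
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 4
        res = dunn_posthoc(values, groups, [("a", "c"), ("b", "c")])
        for pair in res:
            z_expected = oracle_dunn_z(values.tolist(), groups, *pair)
            assert res[pair][0] == pytest.approx(z_expected, abs=1e-12)

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=15)
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        comps = [("a", "c"), ("b", "c")]
        for method in ("bonferroni", "holm", "sidak"):
            adjusted = dunn_posthoc(values, groups, comps, adjust=method)
            raw = dunn_posthoc(values, groups, [comps[0]], adjust="bonferroni")
            assert adjusted[comps[0]][1] >= raw[comps[0]][1] - 1e-12

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            dunn_posthoc([1.0, 2.0], ["a", "b"], [("a", "zzz")])

    def test_agrees_with_permutation_oracle(self):
        """Dunn z translated to p agrees with a permutation null of the
        rank-mean difference on a small instance."""
        rng = np.random.default_rng(12)
        values = rng.normal(0, 1, 12)
        values[8:] += 1.8
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = dunn_posthoc(values, groups, [("c", "a")], adjust="bonferroni")
        z_obs = res[("c", "a")][0]
        p_raw = 2.0 * (1.0 - 0.5 * (1 + math.erf(abs(z_obs) / math.sqrt(2))))
        labels = np.array(groups)
        count = 0
        reps = 4000
        for _ in range(reps):
            perm = rng.permutation(values)
            z = oracle_dunn_z(perm.tolist(), groups, "c", "a")
            count += abs(z) >= abs(z_obs)
        p_mc = count / reps
        se = math.sqrt(p_mc * (1 - p_mc) / reps) + 1e-3
        assert abs(p_mc - p_raw) < 4 * se + 0.02


class TestGroupQuantityTrend:
    def _cohort_ct(self):
        rng = np.random.default_rng(0)
        grid = rng.uniform(22, 30, size=(5, 9))
        return CtMatrix([f"m{i}" for i in range(5)],
                        [f"s{j}" for j in range(9)], grid)

    def test_perfectly_tracking_covariate_gives_unit_r(self):
        ct = self._cohort_ct()
        gm = ct.ct.mean(axis=0)
        anns = [
            SampleAnnotation(f"s{j}", "NGT", clinical={"x": 1000.0 - gm[j] * 10})
            for j in range(9)
        ]
        # covariate is a strictly increasing function of the reversed GM
        trend = group_quantity_trend(ct, anns, ct.assay_ids, clinical_vars=["x"])
        assert trend["x"][0] == pytest.approx(1.0)

    def test_missing_covariate_drops_sample(self):
        ct = self._cohort_ct()
        anns = [
            SampleAnnotation(f"s{j}", "NGT",
                             clinical={} if j == 0 else {"x": float(j)})
            for j in range(9)
        ]
        r, p = group_quantity_trend(ct, anns, ct.assay_ids, clinical_vars=["x"])["x"]
        assert not math.isnan(r)  # computed over the 8 complete samples


class TestCorrelationProfiles:
    def test_single_latent_factor_gives_near_unit_correlations(self):
        cfg = SyntheticConfig(
            seed=5,
            factor_loading_sd={"NGT": 0.0, "NP_IGT": 0.0, "P_IGT": 0.0, "T2D": 0.0},
            noise_sd=1e-3,
            de_effects={},
            coupling={},
        )
        cohort = generate_cohort(cfg)
        from mirpanel import apply_assay_qc
        filtered, report = apply_assay_qc(cohort.ct, cohort.qc_metadata)
        profiles, _ = correlation_profiles(
            filtered, cohort.annotations, report.coexpressed_set
        )
        for prof in profiles.values():
            assert prof.mean_r > 0.99

    def test_pairwise_map_symmetric_with_unit_diagonal(self, default_cohort):
        from mirpanel import apply_assay_qc
        filtered, report = apply_assay_qc(
            default_cohort.ct, default_cohort.qc_metadata
        )
        profiles, cross = correlation_profiles(
            filtered, default_cohort.annotations, report.coexpressed_set
        )
        prof = profiles["NGT"]
        m = prof.pairwise_r.to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert "kruskal" in cross and "dunn_vs_reference" in cross

    def test_undersized_group_skipped(self):
        rng = np.random.default_rng(2)
        ct = CtMatrix(
            [f"m{i}" for i in range(4)],
            ["a1", "a2", "a3", "b1", "b2"],
            rng.uniform(22, 30, size=(4, 5)),
        )
        anns = [SampleAnnotation(s, "NGT") for s in ("a1", "a2", "a3")] + [
            SampleAnnotation(s, "T2D") for s in ("b1", "b2")
        ]
        profiles, _ = correlation_profiles(ct, anns, ct.assay_ids)
        assert "T2D" not in profiles and "NGT" in profiles


class TestLocalVsGlobalSlope:
    def _ct_and_anns(self, assay_row):
        rng = np.random.default_rng(4)
        base = rng.uniform(22, 30, size=(4, 9))
        base[0] = assay_row(base[1:].mean(axis=0))
        ct = CtMatrix(["probe", "m1", "m2", "m3"],
                      [f"s{j}" for j in range(9)], base)
        anns = [SampleAnnotation(f"s{j}", "NGT") for j in range(9)]
        return ct, anns

    def test_assay_equal_to_global_mean_gives_identity_fit(self):
        ct, anns = self._ct_and_anns(lambda gm: gm)
        # global mean over all four rows includes the probe; use the three
        # independent assays as the reference set so probe == f(GM) exactly
        fits = local_vs_global_slope(ct, "probe", anns, ["m1", "m2", "m3"])
        fit = fits["NGT"]
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_constant_assay_gives_zero_slope(self):
        ct, anns = self._ct_and_anns(lambda gm: np.full_like(gm, 25.0))
        fits = local_vs_global_slope(ct, "probe", anns, ["m1", "m2", "m3"])
        assert fits["NGT"].slope == pytest.approx(0.0, abs=1e-10)

    def test_group_specific_coupling_recovered(self):
        """Designated assay generated with per-group coupling 1.0/0.6/0.3
        recovers attenuating slopes (averaged over replicates)."""
        sums = {"NGT": 0.0, "IGT": 0.0, "T2D": 0.0}
        reps = 30
        for seed in range(reps):
            cfg = SyntheticConfig(seed=seed, de_effects={})
            cohort = generate_cohort(cfg)
            from mirpanel import apply_assay_qc
            filtered, report = apply_assay_qc(cohort.ct, cohort.qc_metadata)
            fits = local_vs_global_slope(
                filtered, "sim-miR-27a-3p", cohort.annotations,
                report.coexpressed_set,
            )
            for g in sums:
                sums[g] += fits[g].slope
        means = {g: s / reps for g, s in sums.items()}
        assert abs(means["NGT"] - 1.0) < 0.15
        assert abs(means["IGT"] - 0.6) < 0.15
        assert abs(means["T2D"] - 0.3) < 0.15
        assert means["NGT"] > means["IGT"] > means["T2D"]
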