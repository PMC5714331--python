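"""Contrast lattice, significance categories, signature, group clustering."""

import math

import numpy as np
import pytest

from mirpanel import (
    SampleAnnotation,
    ValidationError,
    categorize,
    cluster_groups,
    run_contrasts,
    select_signature,
    stratify_check,
)
from mirpanel.differential import CONTRASTS, contrast_table
from helpers import make_annotations, make_nrq


def oracle_student_t(a, b):
    """Closed-form pooled-variance two-sample t and two-sided p."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * tdist.sf(abs(t), na + nb - 2)
    return t, p


class TestCategorize:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.05, "n.s."), (0.049999, "*"), (0.01, "*"), (0.009999, "**"),
            (0.001, "**"), (0.000999, "***"), (0.5, "n.s."), (float("nan"), "n.s."),
        ],
    )
    def test_boundaries_exact(self, p, expected):
        assert categorize(p) == expected


class TestRunContrasts:
    def test_identical_groups_give_null_result(self):
        values = {"mir-x": {f"n{i}": 1.0 for i in range(3)}
                  | {f"t{i}": 1.0 for i in range(3)}}
        m = make_nrq(values)
        anns = make_annotations(
            {f"n{i}": "NGT" for i in range(3)} | {f"t{i}": "T2D" for i in range(3)}
        )
        (res,) = run_contrasts(m, anns, contrasts=["T2D_vs_NGT"])
        assert res.t == 0.0 and res.p == 1.0 and res.category == "n.s."
        assert res.direction == 0

    def test_matches_closed_form_student_t(self):
        a, b = [4.0, 5.0, 6.0], [1.0, 2.0, 3.0]
        values = {"mir-x": {f"t{i}": v for i, v in enumerate(a)}
                  | {f"n{i}": v for i, v in enumerate(b)}}
        m = make_nrq(values)
        anns = make_annotations(
            {f"t{i}": "T2D" for i in range(3)} | {f"n{i}": "NGT" for i in range(3)}
        )
        (res,) = run_contrasts(m, anns, contrasts=["T2D_vs_NGT"])
        t_exp, p_exp = oracle_student_t(a, b)
        assert res.t == pytest.approx(t_exp, abs=1e-12)
        assert res.p == pytest.approx(p_exp, abs=1e-12)
        assert res.direction == 1

    def test_t_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 4).tolist()
        b = rng.normal(1, 1, 5).tolist()
        values = {"mir-x": {f"np{i}": v for i, v in enumerate(a)}
                  | {f"p{i}": v for i, v in enumerate(b)}}
        m = make_nrq(values)
        anns = make_annotations(
            {f"np{i}": "NP_IGT" for i in range(4)}
            | {f"p{i}": "P_IGT" for i in range(5)}
        )
        (res,) = run_contrasts(m, anns, contrasts=["NP_vs_P_IGT"])
        swapped = make_annotations(
            {f"np{i}": "P_IGT" for i in range(4)}
            | {f"p{i}": "NP_IGT" for i in range(5)}
        )
        (res2,) = run_contrasts(m, swapped, contrasts=["NP_vs_P_IGT"])
        assert res2.t == pytest.approx(-res.t, abs=1e-12)
        assert res2.p == pytest.approx(res.p, abs=1e-12)

    def test_unknown_contrast_rejected(self):
        m = make_nrq({"mir-x": {"s1": 0.0, "s2": 1.0}})
        with pytest.raises(ValidationError, match="unknown contrast"):
            run_contrasts(m, make_annotations({"s1": "NGT", "s2": "T2D"}),
                          contrasts=["NGT_vs_MARS"])

    def test_igt_umbrella_pools_np_and_p(self):
        rng = np.random.default_rng(1)
        samples = {f"n{i}": "NGT" for i in range(4)}
        samples |= {f"a{i}": "NP_IGT" for i in range(2)}
        samples |= {f"b{i}": "P_IGT" for i in range(2)}
        values = {"mir-x": {s: float(rng.normal()) for s in samples}}
        m = make_nrq(values)
        (res,) = run_contrasts(m, make_annotations(samples), contrasts=["IGT_vs_NGT"])
        pooled = [values["mir-x"][s] for s in samples if samples[s] != "NGT"]
        ref = [values["mir-x"][s] for s in samples if samples[s] == "NGT"]
        t_exp, _ = oracle_student_t(pooled, ref)
        assert res.t == pytest.approx(t_exp, abs=1e-12)

    def test_insufficient_data_skipped(self):
        values = {"mir-x": {"n1": 0.1, "n2": 0.2, "t1": 0.5}}
        m = make_nrq(values)
        anns = make_annotations({"n1": "NGT", "n2": "NGT", "t1": "T2D"})
        assert run_contrasts(m, anns, contrasts=["T2D_vs_NGT"]) == []


class TestSignature:
    def _results(self, categories):
        from mirpanel.differential import ContrastResult

        return [
            ContrastResult(a, c, 0.0, 1.0, cat, 0)
            for (a, c), cat in categories.items()
        ]

    def test_all_ns_gives_empty_set(self):
        res = self._results({("m1", "T2D_vs_NGT"): "n.s."})
        assert select_signature(res) == set()

    def test_single_star_gives_singleton(self):
        res = self._results(
            {("m1", "T2D_vs_NGT"): "*", ("m2", "T2D_vs_NGT"): "n.s."}
        )
        assert select_signature(res) == {"m1"}

    def test_union_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        cats = {}
        for i in range(30):
            for c in CONTRASTS:
                cats[(f"m{i}", c)] = rng.choice(["n.s.", "*", "**"], p=[0.8, 0.15, 0.05])
        res = self._results(cats)
        brute = {a for (a, _c), cat in cats.items() if cat != "n.s."}
        assert select_signature(res) == brute

    def test_monotone_in_contrasts(self):
        res1 = self._results({("m1", "IGT_vs_NGT"): "n.s."})
        res2 = res1 + self._results({("m2", "T2D_vs_NGT"): "*"})
        assert select_signature(res1) <= select_signature(res2)


class TestClusterGroups:
    def _nrq_four_groups(self, profiles, n_per_group=3, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        values = {}
        mapping = {}
        for g, prof in profiles.items():
            for i in range(n_per_group):
                s = f"{g}-{i}"
                mapping[s] = g
                for a, v in enumerate(prof):
                    values.setdefault(f"m{a}", {})[s] = v + rng.normal(0, noise)
        return make_nrq(values), make_annotations(mapping)

    def test_identical_profiles_merge_first_at_zero_height(self):
        profiles = {
            "NGT": [0.0, 0.0], "NP_IGT": [5.0, 5.0],
            "P_IGT": [1.0, 1.0], "T2D": [1.0, 1.0],
        }
        m, anns = self._nrq_four_groups(profiles)
        dend = cluster_groups(m, anns, ["m0", "m1"])
        assert dend.merge_partners() == {"P_IGT", "T2D"}
        assert dend.merge_order[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_dendrogram_invariant_to_sample_order(self):
        profiles = {
            "NGT": [0.0, 1.0], "NP_IGT": [4.0, 2.0],
            "P_IGT": [1.1, 1.4], "T2D": [1.2, 1.3],
        }
        m, anns = self._nrq_four_groups(profiles, noise=0.1)
        d1 = cluster_groups(m, anns, ["m0", "m1"])
        d2 = cluster_groups(m, list(reversed(anns)), ["m0", "m1"])
        assert d1.merge_partners() == d2.merge_partners()
        assert d1.newick() == d2.newick()

    def test_merge_heights_non_decreasing(self):
        profiles = {
            "NGT": [0.0, 1.0], "NP_IGT": [4.0, 2.0],
            "P_IGT": [1.1, 1.4], "T2D": [1.2, 1.3],
        }
        m, anns = self._nrq_four_groups(profiles, noise=0.2, seed=3)
        dend = cluster_groups(m, anns, ["m0", "m1"])
        heights = [h for _, _, h in dend.merge_order]
        assert heights == sorted(heights)

    def test_empty_signature_rejected(self):
        m, anns = self._nrq_four_groups({"NGT": [0.0], "T2D": [1.0]})
        with pytest.raises(ValidationError):
            cluster_groups(m, anns, [])


class TestStratifyCheck:
    def _cohort(self, bmi_by_sample, values, groups):
        anns = [
            SampleAnnotation(s, groups[s], clinical={"bmi_kg_m2": bmi_by_sample[s]})
            for s in groups
        ]
        return make_nrq(values), anns

    def test_strata_matching_groups_reproduce_t_statistics(self):
        rng = np.random.default_rng(5)
        groups = {f"n{i}": "NGT" for i in range(4)}
        groups |= {f"t{i}": "T2D" for i in range(4)}
        values = {"mir-x": {s: float(rng.normal()) for s in groups}}
        bmi = {s: (22.0 if g == "NGT" else 30.0) for s, g in groups.items()}
        m, anns = self._cohort(bmi, values, groups)
        strat = stratify_check(m, anns, cutpoints=[25.0])
        direct = run_contrasts(m, anns, contrasts=["T2D_vs_NGT"])
        assert len(strat) == 1
        assert strat[0].t == pytest.approx(direct[0].t, abs=1e-12)
        assert strat[0].p == pytest.approx(direct[0].p, abs=1e-12)

    def test_single_stratum_rejected(self):
        groups = {f"n{i}": "NGT" for i in range(4)}
        values = {"mir-x": {s: 1.0 for s in groups}}
        bmi = {s: 22.0 for s in groups}
        m, anns = self._cohort(bmi, values, groups)
        with pytest.raises(ValidationError, match="strata"):
            stratify_check(m, anns, cutpoints=[25.0])

    def test_group_effect_invisible_to_bmi_strata(self):
        """Effects injected along the diagnostic axis with BMI assigned
        independently: BMI strata show no systematic signal."""
        rng = np.random.default_rng(8)
        groups = {f"n{i}": "NGT" for i in range(9)}
        groups |= {f"t{i}": "T2D" for i in range(9)}
        values = {
            f"mir-{k}": {
                s: float(rng.normal(1.5 if groups[s] == "T2D" else 0.0, 0.5))
                for s in groups
            }
            for k in range(10)
        }
        bmi = {s: float(rng.uniform(20, 35)) for s in groups}  # independent
        m, anns = self._cohort(bmi, values, groups)
        strat = stratify_check(m, anns, cutpoints=[27.0])
        frac_sig = np.mean([r.category != "n.s." for r in strat])
        assert frac_sig <= 0.3


def test_contrast_table_mirrors_lattice_layout():
    rng = np.random.default_rng(0)
    samples = {}
    for g, n in (("NGT", 3), ("NP_IGT", 3), ("P_IGT", 3), ("T2D", 3)):
        for i in range(n):
            samples[f"{g}{i}"] = g
    values = {
        f"m{k}": {s: float(rng.normal()) for s in samples} for k in range(4)
    }
    m = make_nrq(values)
    res = run_contrasts(m, make_annotations(samples))
    frame = contrast_table(res)
    assert list(frame.columns[:6]) == ["assay_id", *CONTRASTS]
    assert len(frame) == 4
    assert set(frame["IGT_vs_NGT"]) <= {"n.s.", "*", "**", "***"}
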